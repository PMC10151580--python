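"""Triad enumeration, mediation profiles and covariate adjustment."""

import numpy as np
import pandas as pd
import pytest

from transomics import (
    CollinearControlError,
    DegenerateDataError,
    OmicsLayer,
    SyntheticSpec,
    Triad,
    covariate_analysis,
    find_triads,
    generate_dataset,
    harmonize,
    mediation_profile,
    packaged_metadata,
)
from transomics.mediation import classify_mediation
from transomics.screening import ScreenResult
from transomics.stats import CorrelationResult

from conftest import planted_triad_positions, run_screens

SAMPLES = ["S01", "S02", "S03", "C01", "C02", "C03"]


def fake_result(fa, la, fb, lb, significant):
    return CorrelationResult(factor_a=fa, layer_a=la, factor_b=fb, layer_b=lb,
                             n=6, df=4, r=0.95 if significant else 0.1,
                             t=5.0, alpha=0.01, r_crit=0.91719,
                             significant=significant)


def fake_screen(la, lb, sig_pairs, all_pairs):
    return ScreenResult(
        layer_a=la, layer_b=lb, alpha=0.01,
        results=[fake_result(a, la, b, lb, (a, b) in sig_pairs)
                 for a, b in all_pairs],
    )


class TestFindTriads:
    def test_single_closed_triangle(self):
        screens = [
            fake_screen("L1", "L2", {("f1", "g1")}, [("f1", "g1"), ("f2", "g1")]),
            fake_screen("L1", "L3", {("f1", "p1")}, [("f1", "p1")]),
            fake_screen("L2", "L3", {("g1", "p1")}, [("g1", "p1")]),
        ]
        triads = find_triads(screens)
        assert triads == [Triad(x=("L1", "f1"), y=("L2", "g1"),
                                z=("L3", "p1"))]

    def test_open_triangle_yields_nothing(self):
        screens = [
            fake_screen("L1", "L2", {("f1", "g1")}, [("f1", "g1")]),
            fake_screen("L1", "L3", {("f1", "p1")}, [("f1", "p1")]),
            fake_screen("L2", "L3", set(), [("g1", "p1")]),  # edge missing
        ]
        assert find_triads(screens) == []

    def test_two_factors_sharing_partners_give_two_triads(self):
        pairs12 = [("f1", "g1"), ("f2", "g1")]
        screens = [
            fake_screen("L1", "L2", set(pairs12), pairs12),
            fake_screen("L1", "L3", {("f1", "p1"), ("f2", "p1")},
                        [("f1", "p1"), ("f2", "p1")]),
            fake_screen("L2", "L3", {("g1", "p1")}, [("g1", "p1")]),
        ]
        triads = find_triads(screens)
        assert len(triads) == 2
        assert [t.x for t in triads] == [("L1", "f1"), ("L1", "f2")]

    def test_orientation_of_screens_does_not_matter(self):
        screens = [
            fake_screen("L2", "L1", {("g1", "f1")}, [("g1", "f1")]),
            fake_screen("L3", "L1", {("p1", "f1")}, [("p1", "f1")]),
            fake_screen("L2", "L3", {("g1", "p1")}, [("g1", "p1")]),
        ]
        assert len(find_triads(screens)) == 1

    def test_wrong_screen_set_rejected(self):
        s = fake_screen("L1", "L2", set(), [("f1", "g1")])
        with pytest.raises(ValueError):
            find_triads([s, s])
        with pytest.raises(ValueError):
            find_triads([
                s,
                fake_screen("L1", "L3", set(), [("f1", "p1")]),
                fake_screen("L1", "L4", set(), [("f1", "q1")]),
            ])


def triad_dataset(x, y, z, extra=None):
    """Three single-factor layers built from explicit vectors."""
    n = len(x)
    samples = [f"S{i + 1:02d}" for i in range(n // 2)] + \
              [f"C{i + 1:02d}" for i in range(n - n // 2)]
    meta = pd.DataFrame({
        "diagnosis": ["SCZ"] * (n // 2) + ["CON"] * (n - n // 2),
        "age": np.linspace(60, 90, n), "sex": "Male",
        "pmi": 10.0, "doi": 0.0,
        "cpeq": [300.0] * (n // 2) + [0.0] * (n - n // 2),
        "cause_of_death": "synthetic",
    }, index=pd.Index(samples, name="sample_id"))
    layers = [
        OmicsLayer("La", pd.DataFrame([x], index=["fx"], columns=samples)),
        OmicsLayer("Lb", pd.DataFrame([y], index=["fy"], columns=samples)),
        OmicsLayer("Lc", pd.DataFrame([z], index=["fz"], columns=samples)),
    ]
    if extra is not None:
        layers[2].values.loc["fz2"] = extra
    return harmonize(layers, meta)


TRIAD = Triad(x=("La", "fx"), y=("Lb", "fy"), z=("Lc", "fz"))


class TestMediationProfile:
    def test_pure_mediation_recovered(self):
        rng = np.random.default_rng(42)
        z = rng.standard_normal(1000)
        x = 0.95 * z + np.sqrt(1 - 0.95 ** 2) * rng.standard_normal(1000)
        y = 0.95 * z + np.sqrt(1 - 0.95 ** 2) * rng.standard_normal(1000)
        rep = mediation_profile(triad_dataset(x, y, z), TRIAD)
        assert abs(rep.r_xy) > 0.85
        assert abs(rep.partial_xy_z) < 0.1
        assert rep.classification == "mediated-by-z"

    def test_direct_edge_recovered(self):
        rng = np.random.default_rng(43)
        x = rng.standard_normal(1000)
        y = 0.95 * x + np.sqrt(1 - 0.95 ** 2) * rng.standard_normal(1000)
        z = rng.standard_normal(1000)
        rep = mediation_profile(triad_dataset(x, y, z), TRIAD)
        assert rep.partial_xy_z == pytest.approx(rep.r_xy, abs=0.05)
        assert rep.classification == "direct"

    def test_duplicate_control_is_collinear(self):
        x = np.array([1.0, 2.0, 3.0, 4.0, 5.0, 6.5])
        y = np.array([2.0, 1.0, 4.0, 3.0, 6.0, 5.0])
        rep_ds = triad_dataset(x, y, x.copy())
        with pytest.raises(CollinearControlError):
            mediation_profile(rep_ds, TRIAD)

    def test_insufficient_triple_overlap(self):
        x = np.array([1.0, 2.0, 3.0, np.nan, np.nan, np.nan])
        y = np.array([2.0, 1.0, 4.0, 3.0, 6.0, 5.0])
        z = np.array([1.5, 2.5, 3.1, 4.0, 5.0, 6.0])
        from transomics import InsufficientOverlapError
        with pytest.raises(InsufficientOverlapError):
            mediation_profile(triad_dataset(x, y, z), TRIAD)

    def test_partials_match_residual_oracle(self):
        from test_stats import residual_correlation
        rng = np.random.default_rng(7)
        x, y, z = rng.standard_normal((3, 40))
        rep = mediation_profile(triad_dataset(x, y, z), TRIAD)
        assert rep.partial_xy_z == pytest.approx(
            residual_correlation(x, y, z), abs=1e-9)
        assert rep.partial_xz_y == pytest.approx(
            residual_correlation(x, z, y), abs=1e-9)
        assert rep.partial_yz_x == pytest.approx(
            residual_correlation(y, z, x), abs=1e-9)

    def test_relabeling_permutes_consistently(self):
        rng = np.random.default_rng(42)
        z = rng.standard_normal(500)
        x = 0.95 * z + 0.312 * rng.standard_normal(500)
        y = 0.95 * z + 0.312 * rng.standard_normal(500)
        ds = triad_dataset(x, y, z)
        rep = mediation_profile(ds, TRIAD)
        assert rep.classification == "mediated-by-z"
        # put the mediator in the x slot instead
        permuted = Triad(x=("Lc", "fz"), y=("La", "fx"), z=("Lb", "fy"))
        rep_p = mediation_profile(ds, permuted)
        assert rep_p.classification == "mediated-by-x"
        assert rep_p.partial_yz_x == pytest.approx(rep.partial_xy_z, abs=1e-12)

    def test_small_n_distributional_signature(self):
        """At n = 6 with strong loadings, the partial controlling the planted
        mediator collapses relative to the marginal, as a median over seeds."""
        marginals, partials = [], []
        for seed in range(40):
            ds = generate_dataset(SyntheticSpec(seed=seed)).harmonized()
            pos = planted_triad_positions(
                generate_dataset(SyntheticSpec(seed=seed)).truth)
            layers = sorted(ds.layers)
            t = Triad(
                x=(layers[0], ds.layers[layers[0]].factors[0]),
                y=(layers[1], ds.layers[layers[1]].factors[0]),
                z=(layers[2], ds.layers[layers[2]].factors[0]),
            )
            rep = mediation_profile(ds, t)
            # the driver sits at position `pos['z']`; read off the pair NOT
            # involving it and its controlling partial
            pair = {"x": (rep.r_yz, rep.partial_yz_x),
                    "y": (rep.r_xz, rep.partial_xz_y),
                    "z": (rep.r_xy, rep.partial_xy_z)}[pos["z"]]
            marginals.append(abs(pair[0]))
            partials.append(abs(pair[1]))
        assert np.median(partials) < 0.5 * np.median(marginals)
        assert np.median(marginals) > 0.8


class TestClassifyMediation:
    @pytest.mark.parametrize("pxy, pxz, pyz, expected", [
        (0.1, 0.7, 0.7, "mediated-by-z"),
        (0.7, 0.1, 0.7, "mediated-by-y"),
        (0.7, 0.7, 0.1, "mediated-by-x"),
        (0.7, 0.7, 0.7, "direct"),
        (0.1, 0.1, 0.1, "indeterminate"),
        (0.6, 0.2, 0.2, "direct"),  # x-y link survives, others weak
    ])
    def test_rule_table(self, pxy, pxz, pyz, expected):
        assert classify_mediation(pxy, pxz, pyz) == expected

    def test_thresholds_configurable(self):
        assert classify_mediation(0.35, 0.7, 0.7,
                                  drop_threshold=0.4) == "mediated-by-z"


class TestCovariateAnalysis:
    def test_confounded_cohort_partial_collapses(self):
        ds = generate_dataset(
            SyntheticSpec(n_scz=500, n_con=500, structure="confounded",
                          seed=21)
        ).harmonized()
        t = Triad(x=("lipidomics", "lipid_001"),
                  y=("proteomics", "protein_001"),
                  z=("transcriptomics", "gene_001"))
        reports = covariate_analysis(ds, t, covariates=("CPeq",))
        by_factor = {r.factor: r for r in reports}
        # x (lipid) and y-in-generator-terms (gene) are both CPeq-driven
        assert abs(by_factor["lipid_001"].r_marginal) > 0.8
        partial = by_factor["lipid_001"].partials[
            ("transcriptomics", "gene_001")]
        marginal_xy = np.corrcoef(
            ds.layers["lipidomics"].values.loc["lipid_001"],
            ds.layers["transcriptomics"].values.loc["gene_001"])[0, 1]
        assert abs(marginal_xy) > 0.8
        assert abs(partial) < 0.1

    def test_independent_covariate_leaves_partial_alone(self):
        ds = generate_dataset(
            SyntheticSpec(n_scz=500, n_con=500, structure="direct", seed=22)
        ).harmonized()
        t = Triad(x=("lipidomics", "lipid_001"),
                  y=("proteomics", "protein_001"),
                  z=("transcriptomics", "gene_001"))
        reports = covariate_analysis(ds, t, covariates=("AoD",))
        rep = next(r for r in reports if r.factor == "lipid_001")
        marginal = np.corrcoef(
            ds.layers["lipidomics"].values.loc["lipid_001"],
            ds.layers["transcriptomics"].values.loc["gene_001"])[0, 1]
        partial = rep.partials[("transcriptomics", "gene_001")]
        assert partial == pytest.approx(marginal, abs=0.05)

    def test_degenerate_covariate_rejected(self):
        # an all-control cohort has CPeq identically zero
        ds = generate_dataset(
            SyntheticSpec(n_scz=0, n_con=6, structure="null", seed=1)
        ).harmonized()
        t = Triad(x=("lipidomics", "lipid_001"),
                  y=("proteomics", "protein_001"),
                  z=("transcriptomics", "gene_001"))
        with pytest.raises(DegenerateDataError, match="covariate"):
            covariate_analysis(ds, t, covariates=("CPeq",))

    def test_missing_scz_dose_rejected(self):
        from transomics import ValidationError
        ds = generate_dataset(SyntheticSpec(seed=2)).harmonized()
        ds.metadata.loc["S01", "cpeq"] = np.nan
        t = Triad(x=("lipidomics", "lipid_001"),
                  y=("proteomics", "protein_001"),
                  z=("transcriptomics", "gene_001"))
        with pytest.raises(ValidationError, match="CPeq missing"):
            covariate_analysis(ds, t, covariates=("CPeq",))
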