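"""Triad finding and partial-correlation mediation profiling.

Looks for triads — one factor per layer with all three pairwise
correlations individually significant — then computes the three
first-order partials for each triad on the triple-complete samples and
classifies mediation by magnitude: a partial collapsing below 0.30 while
the other two stay at or above 0.50 names the controlled factor as the
mediator. No significance test is attached to the partials at n = 6;
only their sizes are compared.

Reads results/study/; writes results/study/triads.tsv.
"""

import itertools
from pathlib import Path

from transomics import cross_layer_screen, find_triads, mediation_profile
from transomics.mediation import triads_to_frame

ROOT = Path(__file__).resolve().parents[1]

import importlib.util


def _load(name):
    spec = importlib.util.spec_from_file_location(
        name, Path(__file__).parent / f"{name}.py")
    mod = importlib.util.module_from_spec(spec)
    spec.loader.exec_module(mod)
    return mod


screenmod = _load("03_screen_correlations")


def main() -> None:
    ds = screenmod.screened_dataset()
    screens = [cross_layer_screen(ds, a, b, alpha=0.01)
               for a, b in itertools.combinations(screenmod.qc.LAYERS, 2)]
    triads = find_triads(screens)
    reports = [mediation_profile(ds, t) for t in triads]
    out = ROOT / "results" / "study" / "triads.tsv"
    triads_to_frame(reports).to_csv(out, sep="\t", index=False,
                                    lineterminator="\n")
    print(f"{len(reports)} mutually significant triad(s)")
    for rep in reports:
        (lx, fx), (ly, fy), (lz, fz) = rep.triad.members()
        print(f"  {fx} / {fy} / {fz} (n = {rep.n})")
        print(f"    marginals: r_xy = {rep.r_xy:.2f}, "
              f"r_xz = {rep.r_xz:.2f}, r_yz = {rep.r_yz:.2f}")
        print(f"    partials:  r_xy.z = {rep.partial_xy_z:.2f}, "
              f"r_xz.y = {rep.partial_xz_y:.2f}, "
              f"r_yz.x = {rep.partial_yz_x:.2f}")
        print(f"    classification: {rep.classification}")
    print(f"table -> {out}")


if __name__ == "__main__":
    main()
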