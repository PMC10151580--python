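"""Build the study cohort: a 6-sample, 3-layer case-control dataset.

Generates the synthetic cohort every later step analyzes: 3 SCZ and 3 CON
samples measured on 2 lipids, 7 genes and 17 proteins, with

* a planted mediated triad — the first factor of each layer, with the
  proteomics factor as the latent driver and loadings of -0.95 on the
  lipid and the gene (so lipid-gene correlate positively while both
  correlate negatively with the protein),
* opposite case-control shifts (lipid and gene down by 1 SD in SCZ, the
  protein up by 1 SD),
* one lipid observed in only 4 of the 6 samples (reduced overlap), and
* one gross 20-SD outlier injected into a gene.

Outputs: results/study/cohort/ (layer tables, metadata, truth record).
"""

import json
from pathlib import Path

from transomics import SyntheticSpec, generate_dataset

ROOT = Path(__file__).resolve().parents[1]
OUT = ROOT / "results" / "study" / "cohort"

SPEC = SyntheticSpec(
    n_scz=3,
    n_con=3,
    layer_sizes=(2, 7, 17),
    structure="mediated",
    loading_a=-0.95,
    loading_b=-0.95,
    group_shift=(-1.0, -1.0, 1.0),
    missing_pattern={"lipid_002": ("S03", "C03")},
    outlier=("gene_003", "C02", 20.0),
    seed=11,
)


def main() -> None:
    ds = generate_dataset(SPEC, outdir=OUT)
    print(f"cohort written to {OUT}")
    for name, lay in ds.layers.items():
        print(f"  {name}: {len(lay.factors)} factors x {len(lay.samples)} "
              f"samples (min availability "
              f"{int(lay.availability().min())})")
    planted = ds.truth["planted"]
    print("planted structure:", json.dumps(planted, indent=2))


if __name__ == "__main__":
    main()
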