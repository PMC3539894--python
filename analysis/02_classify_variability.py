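"""Scale the variability measures and classify genes.

Noise (DM), plasticity and divergence are scaled to [0,1]; noise and
plasticity are cut at their 25th/75th percentiles into low/medium/high,
giving the joint LNLP/LNHP/HNLP/HNHP classes; noise-sensitive genes
(essential or complex subunits, minus haploinsufficient) are flagged.
"""

from _common import load_dataset, parser, write
from noiseplast.variability import classify_variability


def main() -> None:
    args = parser(__doc__).parse_args()
    ds = load_dataset(args.seed, args.outdir)
    classes = classify_variability(ds.gene_table)
    path = write(classes, args.outdir, "variability_classes.tsv")
    counts = classes["joint_class"].value_counts()
    means = {c: classes[f"{c}_scaled"].mean()
             for c in ("plasticity", "noise", "divergence")}
    print("scaled means: "
          + ", ".join(f"{k}={v:.3f}" for k, v in means.items()))
    print("joint classes: "
          + ", ".join(f"{k}={v}" for k, v in counts.items()))
    print(f"noise-sensitive genes: {int(classes['noise_sensitive'].sum())}")
    print(f"-> {path}")


if __name__ == "__main__":
    main()
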