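"""Generate the synthetic study and write its four input files.

Writes gene_table.tsv, compendium.tsv + mutant_classes.tsv,
transcripts.bed and occupancy.bedgraph under results/data/, plus the
planted-truth sidecar for recovery checks.
"""

from _common import parser
from noiseplast.simulate import SyntheticConfig, generate_dataset


def main() -> None:
    args = parser(__doc__).parse_args()
    cfg = SyntheticConfig(seed=args.seed)
    ds = generate_dataset(cfg)
    outdir = args.outdir / "data"
    ds.write(outdir)
    n_bip = int(ds.transcripts["bipromoter"].sum())
    print(f"wrote {len(ds.gene_table)} genes, "
          f"{len(ds.transcripts)} transcripts "
          f"({n_bip} bipromoter-flagged), "
          f"{ds.compendium.values.shape[1]} mutant profiles -> {outdir}")


if __name__ == "__main__":
    main()
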