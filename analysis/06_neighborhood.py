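"""Genomic-neighborhood architectures and bipromoter effects.

Annotates every gene's upstream partner (orientation, coding status,
intergenic distance, shared-NDR bipromoter), filters dubious/pseudogene
and overlapping partners, summarizes the six architectures, and runs
the bipromoter enrichment tests (essential genes, complex subunits,
LNHP vs HNHP, noise-sensitive HP genes) plus the noise-reduction
contrast in HP genes.
"""

import pandas as pd

from _common import load_dataset, parser, write
from noiseplast.neighborhood import (annotate_neighborhood,
                                     apply_neighborhood_filters,
                                     architecture_summary,
                                     bipromoter_enrichment_tests)
from noiseplast.stats import group_location_tests, spearman
from noiseplast.variability import classify_variability


def main() -> None:
    args = parser(__doc__).parse_args()
    ds = load_dataset(args.seed, args.outdir)
    genes = ds.gene_table
    classes = classify_variability(genes)

    ann = apply_neighborhood_filters(
        annotate_neighborhood(ds.transcripts), genes)
    write(ann, args.outdir, "neighborhood_annotations.tsv")
    excl = ann.loc[ann["excluded"], "exclude_reason"].value_counts()
    print("exclusions: " + ", ".join(f"{k}={v}" for k, v in excl.items()))

    dist = pd.to_numeric(ann["intergenic_distance"], errors="coerce")
    print(f"median intergenic distance: {dist.median():.0f} bp")
    md = ann.merge(genes[["gene_id", "plasticity"]], on="gene_id")
    d = pd.to_numeric(md["intergenic_distance"], errors="coerce")
    rho, p, n = spearman(d[d.notna()], md.loc[d.notna(), "plasticity"])
    print(f"intergenic distance vs plasticity: rho={rho:.2f} "
          f"(p={p:.1e}, n={n})")

    summ = architecture_summary(ann, classes, genes)
    write(summ.labels, args.outdir, "architecture_summary.tsv")
    write(summ.composition.reset_index(), args.outdir,
          "architecture_composition.tsv")
    for r in summ.labels.itertuples(index=False):
        print(f"  {r.architecture:>14}: n={r.n:4d} "
              f"dist={r.mean_intergenic_distance:6.0f} bp "
              f"noise-plasticity rho={r.spearman_rho:+.2f}")

    tests = bipromoter_enrichment_tests(ann, classes, genes)
    write(tests, args.outdir, "bipromoter_enrichment.tsv")
    for r in tests.itertuples(index=False):
        print(f"  bipromoter enrichment {r.test}: OR={r.odds_ratio:.2f} "
              f"p={r.p:.1e} ({r.a}/{r.a + r.b} vs {r.c}/{r.c + r.d})")

    hp_ids = set(classes.loc[classes["plasticity_class"] == "high",
                             "gene_id"])
    m = ann.merge(genes[["gene_id", "noise_dm"]], on="gene_id")
    m = m[m["gene_id"].isin(hp_ids)]
    _, rs_p, mean_bip, mean_rest = group_location_tests(
        m.loc[m["bipromoter"], "noise_dm"],
        m.loc[~m["bipromoter"], "noise_dm"])
    print(f"HP genes: mean noise bipromoter={mean_bip:.4f} vs "
          f"other={mean_rest:.4f} (Wilcoxon p={rs_p:.1e})")


if __name__ == "__main__":
    main()
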