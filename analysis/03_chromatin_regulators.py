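"""CRE/HRE scoring and the regulator-specificity analysis.

Normalizes every mutant profile to unit variance, scores each gene's
chromatin (CRE) and histone (HRE) regulation effect, and builds the
per-regulator table: mean |effect| on HNHP and LNHP normalized by the
HP class, dominant sign, and fraction of genes with decreased
expression.  The planted program mirrors the published contrast:
LNHP-specific activators vs HNHP-specific repressors, and dual-action
histone mutants.
"""

import pandas as pd

from _common import load_dataset, parser, write
from noiseplast.chromatin import (cre_score, ks_group_comparison,
                                  normalize_profiles, regulator_effect_table)
from noiseplast.stats import spearman
from noiseplast.variability import classify_variability


def main() -> None:
    args = parser(__doc__).parse_args()
    ds = load_dataset(args.seed, args.outdir)
    classes = classify_variability(ds.gene_table)
    resp = normalize_profiles(ds.compendium)

    scores = pd.DataFrame({
        "gene_id": ds.gene_table["gene_id"],
        "cre": cre_score(resp, classes=("chromatin",)).to_numpy(),
        "hre": cre_score(resp, classes=("histone",)).to_numpy(),
    })
    write(scores, args.outdir, "cre_scores.tsv")
    rho, p, n = spearman(scores["cre"], ds.gene_table["plasticity"])
    print(f"CRE vs plasticity: Spearman rho={rho:.3f} (p={p:.2e}, n={n})")

    table = regulator_effect_table(resp, classes)
    write(table, args.outdir, "regulator_effects.tsv")
    rho2, p2, _ = spearman(table["ratio_HNHP"], table["ratio_LNHP"])
    print(f"regulator specificity scatter: rho={rho2:.3f} (p={p2:.2e}) — "
          "strong anti-correlation = complementary HNHP/LNHP programs")
    hist = table[table["mutant_class"] == "histone"]
    dual = ((hist["frac_decreased_LNHP"] > 0.5)
            & (hist["frac_decreased_HNHP"] < 0.5)).mean()
    print(f"histone mutants decreasing LNHP while increasing HNHP: "
          f"{100 * dual:.0f}%")

    # the general (TAF1-like) mutants: KS of |effect| in LNHP vs LP genes
    lnhp = classes.loc[classes["joint_class"] == "LNHP", "gene_id"]
    lp = classes.loc[classes["plasticity_class"] == "low", "gene_id"]
    general = resp.mutants_of(["general"])
    ks = ks_group_comparison(resp, general, lnhp, lp)
    write(ks, args.outdir, "general_mutant_lnhp_vs_lp_ks.tsv")
    print(f"general mutants hitting LNHP harder than LP: "
          f"{(ks['ks_p_adj'] < 0.05).sum()}/{len(ks)} at FDR 5%")


if __name__ == "__main__":
    main()
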