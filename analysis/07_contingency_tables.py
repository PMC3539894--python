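"""Recompute the published contingency statistics from printed counts.

The study's 2x2 count tables are published in full, so these statistics
are reproducible exactly without the (undeposited) per-gene source
data: TATA depletion in LP genes (Yates chi-square) and the bipromoter
enrichments (Fisher exact, minimum-likelihood two-sided).
"""

import pandas as pd

from _common import parser, write
from noiseplast.stats import chi2_2x2_yates, fisher_2x2

TABLES = [
    # name, (a, b, c, d), test
    ("tata_lp_vs_rest", (26, 487, 343, 1186), "chi2_yates"),
    ("bipromoter_essential_vs_nonessential", (465, 597, 1651, 2926), "fisher"),
    ("bipromoter_complex_vs_rest", (666, 899, 1486, 2709), "fisher"),
    ("bipromoter_noise_sensitive_HP_vs_tolerant", (79, 158, 67, 207), "fisher"),
    ("bipromoter_LNHP_vs_HNHP", (27, 39, 47, 189), "fisher"),
]


def main() -> None:
    args = parser(__doc__).parse_args()
    rows = []
    for name, (a, b, c, d), kind in TABLES:
        if kind == "chi2_yates":
            stat, p = chi2_2x2_yates(a, b, c, d)
        else:
            stat, p = fisher_2x2(a, b, c, d)
        rows.append({"comparison": name, "a": a, "b": b, "c": c, "d": d,
                     "test": kind, "statistic": stat, "p": p})
        print(f"{name}: {kind} statistic={stat:.3g} p={p:.2g}")
    write(pd.DataFrame(rows), args.outdir, "contingency_tests.tsv")


if __name__ == "__main__":
    main()
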