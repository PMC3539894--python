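"""Sliding-window analysis of translation measures in LP genes.

Low-plasticity genes are ordered by increasing noise and translational
efficiency, ribosome density and ORF length are averaged in a window
slid one gene at a time; envelopes come from 10000 global shuffles.
If noise in poorly transcriptionally-regulated genes is translational
in origin, TE and ribosome density should climb with noise while ORF
length falls.
"""

import numpy as np
import pandas as pd

from _common import load_dataset, parser, write
from noiseplast.stats import sliding_window, spearman
from noiseplast.variability import classify_variability


def main() -> None:
    args = parser(__doc__).parse_args()
    ds = load_dataset(args.seed, args.outdir)
    genes = ds.gene_table
    classes = classify_variability(genes)
    lp = genes[(classes["plasticity_class"] == "low").to_numpy()]

    for col in ("translational_efficiency", "ribosome_density",
                "orf_length"):
        res = sliding_window(lp["noise_dm"].to_numpy(),
                             lp[col].to_numpy(dtype=float),
                             window_size=100, n_perm=10000, seed=args.seed)
        out = pd.DataFrame({"position": np.arange(res.n_windows),
                            "window_mean": res.window_mean,
                            "null_mean": res.null_mean,
                            "null_sd": res.null_sd,
                            "outside": res.outside_envelope()})
        write(out, args.outdir, f"sliding_window_{col}.tsv")
        trend = res.window_mean[-1] - res.window_mean[0]
        frac_out = res.outside_envelope().mean()
        print(f"{col}: first-window {res.window_mean[0]:.2f} -> "
              f"last {res.window_mean[-1]:.2f} "
              f"({'rising' if trend > 0 else 'falling'} with noise), "
              f"{100 * frac_out:.0f}% of positions outside the envelope")

    ok = lp["translational_efficiency"].notna()
    rho, p, n = spearman(lp.loc[ok, "noise_dm"],
                         lp.loc[ok, "translational_efficiency"])
    print(f"noise vs TE in LP genes: rho={rho:.2f} (p={p:.1e}, n={n})")


if __name__ == "__main__":
    main()
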