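"""Variability scaling and classification.

Noise (DM), plasticity and divergence are scaled to [0, 1] on the full
table, then noise and plasticity are each cut into low / medium / high
classes at the 25th and 75th percentiles.  Joint classes combine the two
margins: LNLP, LNHP, HNLP, HNHP, with any medium component mapping to
``other``.  Noise-sensitive genes are essential genes or protein-complex
subunits, excluding haploinsufficient genes.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

__all__ = [
    "scale_unit_interval", "classify_three_way", "joint_class",
    "define_noise_sensitive", "classify_variability",
]

JOINT_LABELS = ("LNLP", "LNHP", "HNLP", "HNHP", "other")


def scale_unit_interval(values) -> pd.Series:
    """Min-max scale to [0, 1]; missing propagates, constant input errors."""
    s = pd.Series(values, dtype=float)
    obs = s.dropna()
    if len(obs) < 2:
        raise ValueError("need at least 2 non-missing values to scale")
    lo, hi = obs.min(), obs.max()
    if hi == lo:
        raise ValueError("degenerate range: all values equal")
    return (s - lo) / (hi - lo)


def classify_three_way(values, p_low: float = 25.0, p_high: float = 75.0,
                       method: str = "linear") -> pd.Series:
    """Cut values into low/medium/high at the p_low and p_high percentiles.

    Strict inequalities: values at either boundary are medium.  Percentiles
    use linear interpolation between closest ranks by default.  Missing
    values stay unclassified (NA).
    """
    if p_low >= p_high:
        raise ValueError(f"p_low ({p_low}) must be < p_high ({p_high})")
    s = pd.Series(values, dtype=float)
    obs = s.dropna()
    if len(obs) < 4:
        raise ValueError("need at least 4 non-missing values to classify")
    lo = np.percentile(obs, p_low, method=method)
    hi = np.percentile(obs, p_high, method=method)
    out = pd.Series(pd.NA, index=s.index, dtype=object)
    out[s < lo] = "low"
    out[s > hi] = "high"
    out[(s >= lo) & (s <= hi)] = "medium"
    return out


def joint_class(noise_class, plasticity_class):
    """Map (noise, plasticity) class pairs to HNHP/LNHP/HNLP/LNLP/other."""
    def one(n, p):
        if pd.isna(n) or pd.isna(p):
            return pd.NA
        if n == "medium" or p == "medium":
            return "other"
        return ("HN" if n == "high" else "LN") + ("HP" if p == "high" else "LP")

    if isinstance(noise_class, str) or noise_class is pd.NA:
        return one(noise_class, plasticity_class)
    n = pd.Series(noise_class, dtype=object)
    p = pd.Series(plasticity_class, dtype=object)
    return pd.Series([one(a, b) for a, b in zip(n, p)], index=n.index, dtype=object)


def define_noise_sensitive(gene_table: pd.DataFrame) -> pd.Series:
    """(essential OR complex member) AND NOT haploinsufficient.

    Missing flags are treated as False.
    """
    def flag(col):
        if col in gene_table:
            return gene_table[col].fillna(False).astype(bool)
        return pd.Series(False, index=gene_table.index)

    return (flag("essential") | flag("complex_member")) & ~flag("haploinsufficient")


def classify_variability(gene_table: pd.DataFrame, p_low: float = 25.0,
                         p_high: float = 75.0,
                         method: str = "linear") -> pd.DataFrame:
    """Build the full per-gene variability class table.

    Scaling happens on the complete input table before any subsetting;
    each measure is classified on all of its non-missing values.
    """
    out = pd.DataFrame({"gene_id": gene_table["gene_id"]})
    for col, scaled_name in (("noise_dm", "noise_scaled"),
                             ("plasticity", "plasticity_scaled"),
                             ("divergence", "divergence_scaled")):
        if col in gene_table:
            out[scaled_name] = scale_unit_interval(gene_table[col]).to_numpy()
    out["noise_class"] = classify_three_way(
        gene_table["noise_dm"], p_low, p_high, method).to_numpy()
    out["plasticity_class"] = classify_three_way(
        gene_table["plasticity"], p_low, p_high, method).to_numpy()
    out["joint_class"] = joint_class(out["noise_class"],
                                     out["plasticity_class"]).to_numpy()
    out["noise_sensitive"] = define_noise_sensitive(gene_table).to_numpy()
    return out
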