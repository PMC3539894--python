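"""Chromatin-regulation responsiveness scoring and regulator analyses.

Each mutant expression profile (log2 ratios of deletion strain vs wild
type) is normalized to unit variance; the absolute normalized value is a
gene's responsiveness to that perturbation.  The mean responsiveness of
a gene over the chromatin-tagged mutants is its chromatin regulation
effect (CRE); over the histone-tagged mutants, its histone regulation
effect (HRE).  The signed normalized matrix keeps the sense of the
regulation: a negative value means the deletion decreased expression,
i.e. the regulator normally activates the gene.

Regulator-level analyses compare, per mutant, the mean absolute effect
on the high-noise/high-plasticity (HNHP) and low-noise/high-plasticity
(LNHP) subclasses normalized by the whole high-plasticity (HP) class,
the dominant sign of the effect, and the fraction of genes whose
expression decreased.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

from .io import Compendium
from .stats import bh_fdr, group_location_tests

__all__ = [
    "ResponsivenessMatrix", "normalize_profiles", "cre_score",
    "regulator_subclass_ratio", "dominant_effect", "fraction_decreased",
    "ks_group_comparison", "regulator_effect_table",
]


@dataclass
class ResponsivenessMatrix:
    """Unit-variance normalized compendium: signed and absolute views."""

    signed: pd.DataFrame        # genes x mutants, column sample SD = 1
    mutant_class: pd.Series

    @property
    def absolute(self) -> pd.DataFrame:
        return self.signed.abs()

    def mutants_of(self, classes: Iterable[str]) -> list[str]:
        classes = set(classes)
        return [m for m in self.signed.columns if self.mutant_class[m] in classes]


def normalize_profiles(comp: Compendium, center: bool = False) -> ResponsivenessMatrix:
    """Scale every mutant column to unit sample variance.

    The column mean is not subtracted unless ``center`` is set: log2
    ratios are already centered on no-change = 0, and the published
    convention normalizes to unit variance without standardizing.
    """
    out = {}
    for m in comp.values.columns:
        col = comp.values[m]
        obs = col.dropna()
        if len(obs) < 2:
            raise ValueError(f"mutant {m!r} has fewer than 2 observations")
        sd = obs.std(ddof=1)
        if sd == 0:
            raise ValueError(f"mutant {m!r} has zero variance")
        out[m] = (col - obs.mean()) / sd if center else col / sd
    signed = pd.DataFrame(out, index=comp.values.index)
    return ResponsivenessMatrix(signed=signed, mutant_class=comp.mutant_class)


def cre_score(resp: ResponsivenessMatrix,
              classes: Sequence[str] = ("chromatin",),
              min_fraction_observed: float = 0.5) -> pd.Series:
    """Per-gene mean absolute responsiveness over mutants of the classes.

    Genes observed in fewer than ``min_fraction_observed`` of the
    selected mutants get a missing score.
    """
    if not classes:
        raise ValueError("classes must be a non-empty subset of mutant classes")
    mutants = resp.mutants_of(classes)
    if not mutants:
        raise ValueError(f"no mutants in classes {tuple(classes)}")
    sub = resp.absolute[mutants]
    score = sub.mean(axis=1, skipna=True)
    frac = sub.notna().mean(axis=1)
    score[frac < min_fraction_observed] = np.nan
    score.name = "cre"
    return score


def _column(resp: ResponsivenessMatrix, mutant_id: str, gene_set) -> pd.Series:
    col = resp.signed[mutant_id].reindex(gene_set)
    return col.dropna()


def regulator_subclass_ratio(resp: ResponsivenessMatrix, mutant_id: str,
                             subclass_genes, hp_genes):
    """Mean |effect| on a subclass divided by mean |effect| on HP.

    A ratio > 1 means the subclass responds more strongly to this
    regulator than the high-plasticity class as a whole.
    """
    sub = _column(resp, mutant_id, subclass_genes).abs()
    hp = _column(resp, mutant_id, hp_genes).abs()
    if len(sub) == 0 or len(hp) == 0:
        raise ValueError(f"empty gene set for mutant {mutant_id!r}")
    hp_mean = float(hp.mean())
    if hp_mean == 0:
        raise ValueError(f"HP mean responsiveness is 0 for {mutant_id!r}")
    sub_mean = float(sub.mean())
    return sub_mean / hp_mean, sub_mean, hp_mean


def dominant_effect(resp: ResponsivenessMatrix, mutant_id: str, gene_set):
    """Dominant sign of a regulator's effect on a gene set.

    Activating = deletion decreases expression in strictly more than
    half of the observed genes (the regulator normally activates).
    Returns (sign, strength, ambiguous); strength = |mean signed value|;
    an exact 50/50 split is reported repressing with ambiguous=True.
    """
    col = _column(resp, mutant_id, gene_set)
    if len(col) == 0:
        raise ValueError(f"no observations for mutant {mutant_id!r}")
    frac_neg = float((col < 0).mean())
    ambiguous = frac_neg == 0.5
    sign = "activating" if frac_neg > 0.5 else "repressing"
    return sign, float(abs(col.mean())), ambiguous


def fraction_decreased(resp: ResponsivenessMatrix, mutant_id: str, gene_set) -> float:
    """Fraction of observed genes with strictly negative signed response."""
    col = _column(resp, mutant_id, gene_set)
    if len(col) == 0:
        raise ValueError(f"no observations for mutant {mutant_id!r}")
    return float((col < 0).mean())


def ks_group_comparison(resp: ResponsivenessMatrix, mutant_ids: Sequence[str],
                        group_a, group_b) -> pd.DataFrame:
    """Per-mutant KS test of |responsiveness| in group_a vs group_b.

    Benjamini-Hochberg adjustment across the mutant list; reports
    -log10 of the adjusted p.  Mutants with an undersized group get a
    missing result.
    """
    raw = []
    for m in mutant_ids:
        a = _column(resp, m, group_a).abs()
        b = _column(resp, m, group_b).abs()
        if len(a) < 2 or len(b) < 2:
            raw.append(np.nan)
            continue
        ks_p, _, _, _ = group_location_tests(a, b)
        raw.append(ks_p)
    adj = bh_fdr(raw)
    with np.errstate(divide="ignore"):
        neglog = -np.log10(adj)
    return pd.DataFrame({"mutant_id": list(mutant_ids), "ks_p": raw,
                         "ks_p_adj": adj, "neg_log10_p_adj": neglog})


def regulator_effect_table(resp: ResponsivenessMatrix,
                           class_table: pd.DataFrame) -> pd.DataFrame:
    """One row per mutant: subclass ratios, dominant sign, decrease fractions.

    ``class_table`` is a variability class table with gene_id,
    joint_class and plasticity_class columns.  The normalizing HP set is
    the full high-plasticity margin (including medium-noise genes), of
    which HNHP and LNHP are the extreme-noise subclasses.
    """
    by_class = class_table.groupby("joint_class")["gene_id"]
    try:
        hnhp = by_class.get_group("HNHP").tolist()
        lnhp = by_class.get_group("LNHP").tolist()
    except KeyError as exc:
        raise ValueError(f"class table lacks genes in class {exc}") from exc
    hp = class_table.loc[class_table["plasticity_class"] == "high",
                         "gene_id"].tolist()

    rows = []
    for m in resp.signed.columns:
        row = {"mutant_id": m, "mutant_class": resp.mutant_class[m]}
        try:
            row["ratio_HNHP"], row["mean_abs_HNHP"], row["mean_abs_HP"] = \
                regulator_subclass_ratio(resp, m, hnhp, hp)
            row["ratio_LNHP"], row["mean_abs_LNHP"], _ = \
                regulator_subclass_ratio(resp, m, lnhp, hp)
            sign, strength, ambiguous = dominant_effect(resp, m, hp)
            row.update(dominant_sign=sign, strength=strength,
                       ambiguous=ambiguous)
            row["frac_decreased_HNHP"] = fraction_decreased(resp, m, hnhp)
            row["frac_decreased_LNHP"] = fraction_decreased(resp, m, lnhp)
        except ValueError:
            # mutant unobserved in a required gene set: report as missing
            for key in ("ratio_HNHP", "mean_abs_HNHP", "mean_abs_HP",
                        "ratio_LNHP", "mean_abs_LNHP", "strength",
                        "frac_decreased_HNHP", "frac_decreased_LNHP"):
                row.setdefault(key, np.nan)
            row.setdefault("dominant_sign", pd.NA)
            row.setdefault("ambiguous", pd.NA)
        rows.append(row)
    return pd.DataFrame(rows)
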