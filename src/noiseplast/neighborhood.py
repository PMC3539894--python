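"""Genomic-neighborhood architecture of each gene.

For a focal transcript, the upstream partner is the nearest transcript
lying before the TSS in the focal gene's reading direction.  The
orientation is parallel when the partner is on the same strand (its TES
faces the focal TSS) and divergent otherwise (its TSS faces the focal
TSS — an opposite-strand upstream transcript necessarily points away).
Intergenic distance is measured from the focal TSS to the partner's
facing edge.  Architectures combine orientation, a shared-NDR
bipromoter annotation, and whether the partner is coding (ORF-T) or
noncoding (CUT/SUT).

Filters mirror the published data hygiene: genes whose upstream partner
is a dubious ORF or pseudogene, or whose nearest upstream transcript
overlaps the focal span, are excluded from architecture summaries.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import NamedTuple, Optional

import numpy as np
import pandas as pd

from .stats import fisher_2x2, spearman

__all__ = [
    "find_upstream_partner", "intergenic_distance",
    "apply_neighborhood_filters", "architecture_label",
    "annotate_neighborhood", "architecture_summary", "ArchitectureSummary",
    "ARCHITECTURE_LABELS",
]

ARCHITECTURE_LABELS = ("bipromoter_C", "bipromoter_NC", "divergent_C",
                       "divergent_NC", "parallel_C", "parallel_NC")


class PartnerHit(NamedTuple):
    partner_id: Optional[str]
    orientation: str            # divergent | parallel | none
    facing_edge: Optional[int]  # genomic coordinate of the partner edge
    overlap: bool               # partner span overlaps the focal span


def _span(row) -> tuple[int, int]:
    return min(row.tss, row.tes), max(row.tss, row.tes)


def find_upstream_partner(focal, candidates: pd.DataFrame) -> PartnerHit:
    """Nearest transcript upstream of the focal TSS.

    ``candidates`` must share the focal chromosome and exclude the focal
    transcript itself.  The partner is the candidate whose focal-facing
    edge lies nearest upstream of the focal TSS (ties broken by
    lexicographic transcript_id).  A partner whose span reaches into the
    focal span is still returned, flagged ``overlap`` for downstream
    exclusion.
    """
    flo, fhi = _span(focal)
    if len(candidates) == 0:
        return PartnerHit(None, "none", None, False)
    lo = np.minimum(candidates["tss"].to_numpy(), candidates["tes"].to_numpy())
    hi = np.maximum(candidates["tss"].to_numpy(), candidates["tes"].to_numpy())
    ids = candidates["transcript_id"].to_numpy()
    strands = candidates["strand"].to_numpy()

    if focal.strand == "+":
        elig = lo < flo                      # starts upstream (to the left)
        edges = hi                           # right edge faces the focal TSS
        best = -np.inf
        better = lambda e, b: e > b
    else:
        elig = hi > fhi                      # starts upstream (to the right)
        edges = lo                           # left edge faces the focal TSS
        best = np.inf
        better = lambda e, b: e < b

    choice = None
    for i in np.flatnonzero(elig):
        e = edges[i]
        if choice is None or better(e, best) or (e == best and ids[i] < ids[choice]):
            choice, best = i, e
    if choice is None:
        return PartnerHit(None, "none", None, False)

    orientation = "parallel" if strands[choice] == focal.strand else "divergent"
    overlap = bool(hi[choice] >= flo and lo[choice] <= fhi)
    return PartnerHit(str(ids[choice]), orientation, int(edges[choice]), overlap)


def intergenic_distance(focal, partner, mode: str = "facing_edge") -> int:
    """bp between the focal TSS and the upstream partner.

    ``facing_edge``: |focal TSS - partner facing edge| (partner TSS for
    divergent pairs, TES for parallel).  ``span_gap``: gap between the
    two transcript spans.  Overlapping pairs are an error; they must be
    excluded upstream.
    """
    flo, fhi = _span(focal)
    plo, phi = _span(partner)
    if phi >= flo and plo <= fhi:
        raise ValueError("overlapping transcripts have no intergenic distance")
    if mode == "span_gap":
        return int(flo - phi - 1 if phi < flo else plo - fhi - 1)
    edge = phi if focal.strand == "+" else plo
    return int(abs(int(focal.tss) - edge))


def architecture_label(orientation: str, partner_kind: str,
                       bipromoter: bool) -> str:
    """bipromoter/divergent/parallel x coding/noncoding label."""
    if bipromoter and orientation != "divergent":
        raise ValueError("bipromoter annotation requires divergent orientation")
    suffix = "_C" if partner_kind == "ORF_T" else "_NC"
    stem = "bipromoter" if bipromoter else orientation
    return stem + suffix


def annotate_neighborhood(transcripts: pd.DataFrame,
                          focal_ids=None,
                          distance_mode: str = "facing_edge") -> pd.DataFrame:
    """Per-gene neighborhood annotation over a transcript set.

    Focal transcripts default to all verified ORF-Ts; all transcript
    kinds (including CUTs/SUTs and decoys) act as partner candidates.
    """
    ts = transcripts.reset_index(drop=True)
    if focal_ids is None:
        focal = ts[(ts["kind"] == "ORF_T") & (ts["status"] == "verified")]
    else:
        focal = ts[ts["transcript_id"].isin(set(focal_ids))]
    by_id = ts.set_index("transcript_id")
    by_chrom = {c: g for c, g in ts.groupby("chrom")}

    rows = []
    for f in focal.itertuples(index=False):
        cands = by_chrom[f.chrom]
        cands = cands[cands["transcript_id"] != f.transcript_id]
        hit = find_upstream_partner(f, cands)
        row = {"gene_id": f.transcript_id, "partner_id": hit.partner_id,
               "orientation": hit.orientation, "partner_coding": pd.NA,
               "intergenic_distance": pd.NA,
               "bipromoter": bool(f.bipromoter),
               "excluded": False, "exclude_reason": pd.NA,
               "architecture": pd.NA}
        if hit.partner_id is None:
            row.update(excluded=True, exclude_reason="no_partner")
        else:
            partner = by_id.loc[hit.partner_id]
            row["partner_coding"] = partner["kind"] == "ORF_T"
            if partner["status"] in ("dubious", "pseudogene"):
                row.update(excluded=True,
                           exclude_reason=partner["status"] + "_partner")
            elif hit.overlap:
                row.update(excluded=True, exclude_reason="overlap")
            else:
                row["intergenic_distance"] = intergenic_distance(
                    f, partner, distance_mode)
                row["architecture"] = architecture_label(
                    hit.orientation, partner["kind"], bool(f.bipromoter))
        rows.append(row)
    return pd.DataFrame(rows)


def apply_neighborhood_filters(annotations: pd.DataFrame,
                               gene_table: pd.DataFrame | None = None
                               ) -> pd.DataFrame:
    """Flag genes that cannot enter architecture summaries.

    Partner-based exclusions (dubious/pseudogene partner, overlap, no
    partner) are already produced by :func:`annotate_neighborhood`; this
    adds ``missing_coords`` for gene-table genes without a transcript
    record.
    """
    out = annotations.copy()
    if gene_table is not None:
        known = set(out["gene_id"])
        missing = [g for g in gene_table["gene_id"] if g not in known]
        if missing:
            extra = pd.DataFrame({
                "gene_id": missing, "partner_id": pd.NA,
                "orientation": "none", "partner_coding": pd.NA,
                "intergenic_distance": pd.NA, "bipromoter": False,
                "excluded": True, "exclude_reason": "missing_coords",
                "architecture": pd.NA})
            out = pd.concat([out, extra], ignore_index=True)
    return out


@dataclass
class ArchitectureSummary:
    """Per-architecture coupling statistics and class composition."""

    labels: pd.DataFrame         # one row per architecture label
    composition: pd.DataFrame    # joint_class x architecture, percent


def architecture_summary(annotations: pd.DataFrame,
                         class_table: pd.DataFrame,
                         gene_table: pd.DataFrame) -> ArchitectureSummary:
    """Summarize each architecture: n, mean distance, noise-plasticity rho.

    Composition percentages are computed within each joint variability
    class and sum to 100 per class.  Labels with fewer than 4 genes get
    a missing correlation.
    """
    merged = (annotations[~annotations["excluded"]]
              .merge(class_table, on="gene_id", how="left")
              .merge(gene_table[["gene_id", "noise_dm", "plasticity"]],
                     on="gene_id", how="left"))
    rows = []
    for label in ARCHITECTURE_LABELS:
        sub = merged[merged["architecture"] == label]
        dist = pd.to_numeric(sub["intergenic_distance"], errors="coerce")
        row = {"architecture": label, "n": len(sub),
               "mean_intergenic_distance": float(dist.mean()) if len(sub) else np.nan}
        pairs = sub[["noise_dm", "plasticity"]].dropna()
        if len(pairs) >= 4:
            rho, p, n = spearman(pairs["noise_dm"], pairs["plasticity"])
            row.update(spearman_rho=rho, spearman_p=p, n_pairs=n)
        else:
            row.update(spearman_rho=np.nan, spearman_p=np.nan,
                       n_pairs=len(pairs))
        rows.append(row)
    labels = pd.DataFrame(rows)

    comp = (merged.dropna(subset=["joint_class", "architecture"])
            .groupby(["joint_class", "architecture"], observed=True)
            .size().unstack(fill_value=0)
            .reindex(columns=ARCHITECTURE_LABELS, fill_value=0))
    comp = comp.div(comp.sum(axis=1), axis=0) * 100.0

    return ArchitectureSummary(labels=labels, composition=comp)


def bipromoter_enrichment_tests(annotations: pd.DataFrame,
                                class_table: pd.DataFrame,
                                gene_table: pd.DataFrame) -> pd.DataFrame:
    """The bipromoter enrichment contingency tests of the Results.

    Fisher exact tests of bipromoter frequency in: essential vs
    nonessential genes, complex subunits vs the rest, LNHP vs HNHP, and
    noise-sensitive vs noise-tolerant HP genes.
    """
    df = (annotations.merge(class_table, on="gene_id", how="left")
          .merge(gene_table, on="gene_id", how="left"))

    def _bool(s: pd.Series) -> pd.Series:
        return s.astype("boolean").fillna(False).astype(bool)

    bip = _bool(df["bipromoter"])

    def table(mask_a, mask_b):
        a = int((bip & mask_a).sum()); b = int((~bip & mask_a).sum())
        c = int((bip & mask_b).sum()); d = int((~bip & mask_b).sum())
        return a, b, c, d

    def flag(col):
        return _bool(df[col]) if col in df else pd.Series(False, index=df.index)

    hp = df["plasticity_class"] == "high"
    ns = _bool(df["noise_sensitive"])
    tests = {
        "essential_vs_nonessential": table(flag("essential"), ~flag("essential")),
        "complex_vs_rest": table(flag("complex_member"), ~flag("complex_member")),
        "LNHP_vs_HNHP": table(df["joint_class"] == "LNHP",
                              df["joint_class"] == "HNHP"),
        "noise_sensitive_HP_vs_tolerant_HP": table(hp & ns, hp & ~ns),
    }
    rows = []
    for name, (a, b, c, d) in tests.items():
        if min(a + b, c + d, a + c, b + d) == 0:
            rows.append({"test": name, "a": a, "b": b, "c": c, "d": d,
                         "odds_ratio": np.nan, "p": np.nan})
            continue
        odds, p = fisher_2x2(a, b, c, d)
        rows.append({"test": name, "a": a, "b": b, "c": c, "d": d,
                     "odds_ratio": odds, "p": p})
    return pd.DataFrame(rows)
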