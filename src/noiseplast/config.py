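"""Flat analysis configuration.

Every tunable knob of the pipeline lives here so that analyses are
reproducible from a single YAML file.  Defaults mirror the published
analysis conventions (quartile class boundaries, 10 occupancy bins,
10000 randomizations, -100..0 / -400..-150 bp promoter windows).
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import yaml


@dataclass
class AnalysisConfig:
    """Keys controlling every stage of the pipeline.

    Parameters
    ----------
    p_low, p_high
        Percentile boundaries (in percent) for the low/medium/high
        three-way classification of noise and plasticity.
    percentile_method
        Percentile convention, ``"linear"`` interpolation between closest
        ranks (the default in scientific software) or any method name
        accepted by :func:`numpy.percentile`.
    center_columns
        Whether unit-variance normalization of compendium columns also
        subtracts the column mean.  Off by default: log2 ratios are
        already centered on no-change = 0.
    cre_classes, hre_classes
        Mutant classes averaged into the chromatin / histone regulation
        effect scores.
    min_fraction_observed
        Minimum fraction of the selected mutants a gene must be measured
        in to receive a CRE/HRE score.
    min_ratio
        Consumer-side filter for regulator specificity ratios (>1 means
        the subclass responds more strongly than the whole HP class).
    proximal_window, distal_window
        Promoter windows in bp relative to the TSS (inclusive, upstream
        negative).
    window_assignment
        How interval-valued occupancy points are assigned to windows:
        ``"midpoint"`` or ``"overlap_weighted"``.
    n_bins, n_perm
        Occupancy bin count and permutation count for the binned
        permutation test.
    window_size
        Sliding-window width in genes (step is always 1).
    envelope_sd
        Half-width of the significance envelope in null standard
        deviations (the mean +/- 2 SD rule).
    distance_mode
        Intergenic distance convention: ``"facing_edge"`` (TSS to the
        partner edge facing the focal gene) or ``"span_gap"``.
    """

    p_low: float = 25.0
    p_high: float = 75.0
    percentile_method: str = "linear"

    center_columns: bool = False
    cre_classes: tuple[str, ...] = ("chromatin",)
    hre_classes: tuple[str, ...] = ("histone",)
    min_fraction_observed: float = 0.5
    min_ratio: float = 1.0

    proximal_window: tuple[int, int] = (-100, 0)
    distal_window: tuple[int, int] = (-400, -150)
    window_assignment: str = "midpoint"

    n_bins: int = 10
    n_perm: int = 10000
    window_size: int = 100
    envelope_sd: float = 2.0

    distance_mode: str = "facing_edge"

    def __post_init__(self) -> None:
        if self.p_low >= self.p_high:
            raise ValueError(f"p_low ({self.p_low}) must be < p_high ({self.p_high})")
        if self.window_assignment not in ("midpoint", "overlap_weighted"):
            raise ValueError(f"unknown window_assignment: {self.window_assignment!r}")
        if self.distance_mode not in ("facing_edge", "span_gap"):
            raise ValueError(f"unknown distance_mode: {self.distance_mode!r}")

    @classmethod
    def from_yaml(cls, path: str | Path) -> "AnalysisConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(raw) - known
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        for key in ("cre_classes", "hre_classes", "proximal_window", "distal_window"):
            if key in raw and isinstance(raw[key], Sequence) and not isinstance(raw[key], str):
                raw[key] = tuple(raw[key])
        return cls(**raw)

    def to_yaml(self, path: str | Path) -> None:
        with open(path, "w") as fh:
            yaml.safe_dump(
                {k: list(v) if isinstance(v, tuple) else v
                 for k, v in dataclasses.asdict(self).items()},
                fh, sort_keys=True,
            )

    def digest(self) -> str:
        """Short stable hash of the configuration, used in output provenance."""
        blob = json.dumps(dataclasses.asdict(self), sort_keys=True, default=list)
        return hashlib.sha256(blob.encode()).hexdigest()[:12]
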