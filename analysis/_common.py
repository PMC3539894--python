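"""Shared plumbing for the numbered analysis drivers.

Each driver works from the synthetic study written by 01_simulate.py
when it exists, and otherwise regenerates it in memory, so every driver
is runnable standalone.
"""

from __future__ import annotations

import argparse
from pathlib import Path

from noiseplast import io
from noiseplast.simulate import SyntheticConfig, SyntheticDataset, \
    generate_dataset

RESULTS = Path(__file__).resolve().parent.parent / "results"


def parser(description: str) -> argparse.ArgumentParser:
    p = argparse.ArgumentParser(description=description)
    p.add_argument("--seed", type=int, default=1)
    p.add_argument("--outdir", type=Path, default=RESULTS)
    return p


def load_dataset(seed: int, outdir: Path) -> SyntheticDataset:
    data = outdir / "data"
    if (data / "gene_table.tsv").exists():
        genes = io.read_gene_table(data / "gene_table.tsv")
        ts = io.read_transcripts(data / "transcripts.bed")
        track = io.read_occupancy(data / "occupancy.bedgraph")
        comp = io.read_compendium(data / "compendium.tsv",
                                  data / "mutant_classes.tsv")
        return SyntheticDataset(gene_table=genes, transcripts=ts,
                                track=track, compendium=comp)
    return generate_dataset(SyntheticConfig(seed=seed))


def write(df, outdir: Path, name: str) -> Path:
    outdir.mkdir(parents=True, exist_ok=True)
    path = outdir / name
    io.write_result_table(df, path, None)
    return path
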