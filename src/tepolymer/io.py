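"""Plain-text interchange: multi-frame XYZ trajectories, TSV tables, BED
intervals and flat key-value configuration files / run manifests.

All outputs are tool-chain-agnostic text standards. XYZ element tags encode
bead identity (``S`` stiff, ``F`` flexible/soft); the comment line carries
the sweep index and seed. BED intervals are 0-based half-open on the
contig ``substrate``, one interval of ``bp_per_bead`` base pairs per bond
locus.
"""

from __future__ import annotations

from pathlib import Path
from typing import List, Optional, Sequence

import numpy as np
import pandas as pd
import yaml

from .substrate import PolymerConformation, SubstrateSpec
from .integration import ExperimentResult
from .observables import FrequencyProfile

BED_CONTIG = "substrate"


def _soft_bead_mask(spec: SubstrateSpec) -> np.ndarray:
    mask = np.zeros(spec.n_beads, dtype=bool)
    mask[spec.soft_joints()] = True
    return mask


def write_xyz(path, frames: Sequence[PolymerConformation],
              spec: Optional[SubstrateSpec] = None) -> None:
    """Multi-frame XYZ; soft beads tagged F, all others S."""
    frames = list(frames)
    if not frames:
        raise ValueError("no frames to write")
    mask = _soft_bead_mask(spec) if spec is not None \
        else np.zeros(frames[0].n_beads, dtype=bool)
    with open(path, "w") as fh:
        for conf in frames:
            fh.write(f"{conf.n_beads}\n")
            fh.write(f"sweep={conf.metadata.get('sweep', 0)} "
                     f"seed={conf.metadata.get('seed', 0)}\n")
            for b in range(conf.n_beads):
                tag = "F" if mask[b] else "S"
                x, y, z = conf.coords[b]
                fh.write(f"{tag} {x:.8f} {y:.8f} {z:.8f}\n")


def read_xyz(path) -> List[PolymerConformation]:
    """Read a multi-frame XYZ written by :func:`write_xyz`."""
    frames = []
    with open(path) as fh:
        lines = fh.read().splitlines()
    i = 0
    while i < len(lines):
        if not lines[i].strip():
            i += 1
            continue
        n = int(lines[i])
        meta = {}
        for tok in lines[i + 1].split():
            if "=" in tok:
                key, val = tok.split("=", 1)
                try:
                    meta[key] = int(val)
                except ValueError:
                    meta[key] = val
        coords = np.empty((n, 3))
        tags = []
        for b in range(n):
            parts = lines[i + 2 + b].split()
            tags.append(parts[0])
            coords[b] = [float(v) for v in parts[1:4]]
        meta["elements"] = tags
        frames.append(PolymerConformation(coords, meta))
        i += 2 + n
    return frames


def events_dataframe(result: ExperimentResult) -> pd.DataFrame:
    return pd.DataFrame(
        [{"replicate": e.replicate_id, "locus": e.locus,
          "delta_E": e.delta_E, "sweep": e.sweep, "seed": e.seed,
          "flagged": int(e.flagged)} for e in result.events])


def write_events_tsv(path, result: ExperimentResult) -> None:
    events_dataframe(result).to_csv(path, sep="\t", index=False,
                                    float_format="%.10g")


def write_events_bed(path, result: ExperimentResult) -> None:
    """Accepted events as BED intervals [locus*bp, (locus+1)*bp)."""
    bp = result.spec.bp_per_bead
    rows = []
    for e in result.ok_events:
        rows.append((BED_CONTIG, e.locus * bp, (e.locus + 1) * bp,
                     f"rep{e.replicate_id}"))
    with open(path, "w") as fh:
        for chrom, start, end, name in rows:
            fh.write(f"{chrom}\t{start}\t{end}\t{name}\n")


def write_profile_tsv(path, profile: FrequencyProfile,
                      bp_per_bead: int) -> None:
    df = pd.DataFrame({
        "locus": np.arange(profile.n_loci),
        "start_bp": np.arange(profile.n_loci) * bp_per_bead,
        "frequency": profile.freqs,
        "se": profile.se,
    })
    df.to_csv(path, sep="\t", index=False, float_format="%.10g")


def write_table_tsv(path, df: pd.DataFrame) -> None:
    df.to_csv(path, sep="\t", index=False, float_format="%.10g")


def write_manifest(path, mapping: dict) -> None:
    """Flat ``key = value`` manifest; reproducing a run needs nothing else."""
    with open(path, "w") as fh:
        for key in sorted(mapping):
            fh.write(f"{key} = {mapping[key]}\n")


def read_config(path) -> dict:
    """Flat key-value configuration file (YAML mapping of scalars; list
    values may be given as comma-separated strings or YAML lists)."""
    with open(path) as fh:
        data = yaml.safe_load(fh)
    if data is None:
        return {}
    if not isinstance(data, dict):
        raise ValueError(f"configuration file {path} is not a flat mapping")
    for key, val in data.items():
        if isinstance(val, dict):
            raise ValueError(
                f"configuration key {key!r} is nested; the file must be flat")
    return data
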