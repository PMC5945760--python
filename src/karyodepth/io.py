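"""Readers and writers for the pipeline's plain-text formats.

Conventions: binned depth profiles are BED-like TSVs with columns
``chrom  start  end  count`` (0-based half-open, one row per window) plus
a sidecar ``<name>.totals.json`` with per-chromosome totals; chromosome
labels are written as ``Chr01`` … ``Chr12`` and read tolerantly
(``chr1``, ``1``, ``Chr. 1`` all resolve).  idxstats-style tables are
4-column TSVs ``chrom  length  mapped  unmapped`` with an optional
``*`` row for unmapped reads.
"""

from __future__ import annotations

import json
import platform
import re
import sys
from pathlib import Path

import numpy as np

from .genome import GenomeSpec, N_CHROMOSOMES
from .profiles import DepthProfile

__all__ = [
    "read_binned_depth",
    "write_binned_depth",
    "read_idxstats",
    "write_provenance",
    "parse_chrom_label",
]

_CHROM_RE = re.compile(r"^(?:chr\.?\s*)?0*(\d{1,2})$", re.IGNORECASE)


def parse_chrom_label(label: str) -> int:
    m = _CHROM_RE.match(label.strip())
    if m is None:
        raise ValueError(f"unknown chromosome label: {label!r}")
    cid = int(m.group(1))
    if not 1 <= cid <= N_CHROMOSOMES:
        raise ValueError(f"chromosome label out of range 1..{N_CHROMOSOMES}: {label!r}")
    return cid


def format_chrom_label(cid: int) -> str:
    return f"Chr{cid:02d}"


def write_binned_depth(profile: DepthProfile, path: str | Path) -> None:
    """Write a profile as a BED-like TSV plus a totals sidecar JSON."""
    path = Path(path)
    counts = np.asarray(profile.count)
    integral = np.allclose(counts, np.round(counts))
    with open(path, "w") as fh:
        for c, s, e, n in zip(profile.chrom, profile.start, profile.end, counts):
            val = f"{int(round(n))}" if integral else repr(float(n))
            fh.write(f"{format_chrom_label(int(c))}\t{int(s)}\t{int(e)}\t{val}\n")
    totals = profile.chromosome_counts()
    sidecar = {
        "individual_id": profile.individual_id,
        "total_count": float(profile.total_count),
        "chromosome_counts": {
            format_chrom_label(i + 1): float(totals[i]) for i in range(N_CHROMOSOMES)
        },
    }
    with open(path.with_suffix(path.suffix + ".totals.json"), "w") as fh:
        json.dump(sidecar, fh, indent=2, sort_keys=True)


def read_binned_depth(
    path: str | Path, genome: GenomeSpec | None = None, individual_id: str | None = None
) -> DepthProfile:
    """Read a BED-like binned depth TSV into a :class:`DepthProfile`.

    Validates per-chromosome window order and non-overlap; errors name
    the offending line number.  When ``genome`` is given, the windows
    must exactly tile it.
    """
    path = Path(path)
    chroms, starts, ends, counts = [], [], [], []
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            fields = line.split("\t")
            if len(fields) != 4:
                raise ValueError(
                    f"{path}:{lineno}: expected 4 tab-separated columns, got {len(fields)}"
                )
            try:
                cid = parse_chrom_label(fields[0])
                start, end = int(fields[1]), int(fields[2])
                count = float(fields[3])
            except ValueError as exc:
                raise ValueError(f"{path}:{lineno}: {exc}") from exc
            if end <= start:
                raise ValueError(f"{path}:{lineno}: empty or inverted window")
            if count < 0:
                raise ValueError(f"{path}:{lineno}: negative count")
            if chroms and chroms[-1] == cid and start < ends[-1]:
                raise ValueError(
                    f"{path}:{lineno}: window overlaps or precedes the previous "
                    f"window of {fields[0]}"
                )
            chroms.append(cid)
            starts.append(start)
            ends.append(end)
            counts.append(count)
    if not chroms:
        raise ValueError(f"{path}: no windows")
    counts_arr = np.array(counts)
    if np.allclose(counts_arr, np.round(counts_arr)):
        counts_arr = np.round(counts_arr)
    profile = DepthProfile(
        individual_id=individual_id or path.stem,
        chrom=np.array(chroms, dtype=np.int64),
        start=np.array(starts, dtype=np.int64),
        end=np.array(ends, dtype=np.int64),
        count=counts_arr,
    )
    if genome is not None:
        profile.validate_against(genome)
    return profile


def read_idxstats(path: str | Path) -> np.ndarray:
    """Read an idxstats-style TSV into per-chromosome mapped-read counts.

    Layout ``chrom  length  mapped  unmapped``; the ``*`` row is ignored.
    All 12 chromosomes must be present exactly once.
    """
    path = Path(path)
    counts = np.full(N_CHROMOSOMES, -1.0)
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line:
                continue
            fields = line.split("\t")
            if fields[0] == "*":
                continue
            if len(fields) != 4:
                raise ValueError(
                    f"{path}:{lineno}: expected 4 tab-separated columns, got {len(fields)}"
                )
            try:
                cid = parse_chrom_label(fields[0])
                mapped = int(fields[2])
            except ValueError as exc:
                raise ValueError(f"{path}:{lineno}: {exc}") from exc
            if counts[cid - 1] >= 0:
                raise ValueError(f"{path}:{lineno}: duplicate chromosome {fields[0]}")
            counts[cid - 1] = mapped
    missing = [i + 1 for i in range(N_CHROMOSOMES) if counts[i] < 0]
    if missing:
        raise ValueError(f"{path}: missing chromosomes {missing}")
    return counts


def write_provenance(path: str | Path, config: dict, seed: int | None) -> None:
    """Record the run's configuration, seed and software versions."""
    import karyodepth

    prov = {
        "tool": "karyodepth",
        "version": karyodepth.__version__,
        "python": sys.version.split()[0],
        "platform": platform.platform(),
        "numpy": np.__version__,
        "seed": seed,
        "config": config,
    }
    with open(path, "w") as fh:
        json.dump(prov, fh, indent=2, sort_keys=True)
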