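"""Per-genus BLAST e-value profiles ("heat map" matrices).

Hits are binned by e-value into contiguous half-open decade ranges; rows
(genera or custom clade groups) below a minimum total-hit threshold are
dropped.  Conservation holds exactly: accepted + dropped + overflow equals
the input hit count.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Sequence

from .core_io import BlastHit, TaxonGroupMap

__all__ = [
    "ProfileMatrix",
    "default_bin_edges",
    "build_profile",
    "render_profile",
    "read_profile",
]


def default_bin_edges() -> list[float]:
    """Decade edges from 1e0 down to 1e-180 (1e-80 guaranteed present);
    an extra underflow bin catches e-values below 1e-180, including 0."""
    return [10.0 ** (-k) for k in range(0, 181)]


def _bin_labels(edges: Sequence[float]) -> list[str]:
    labels = []
    for i in range(len(edges) - 1):
        labels.append(f"[{edges[i + 1]:.0e},{edges[i]:.0e})")
    labels.append(f"<{edges[-1]:.0e}")
    return labels


@dataclass
class ProfileMatrix:
    """Genus/group x e-value-range hit-count matrix."""

    row_labels: list[str]
    bin_edges: list[float]  # strictly decreasing e-values; last bin is "<min"
    counts: list[list[int]]  # rows x (len(bin_edges)-1+1) cells
    min_hits: int
    total_hits: int  # accepted (in-matrix) hits
    dropped_hits: int = 0
    overflow_hits: int = 0

    @property
    def column_labels(self) -> list[str]:
        return _bin_labels(self.bin_edges)

    @property
    def n_bins(self) -> int:
        return len(self.bin_edges)  # len(edges)-1 range bins + underflow

    def row(self, label: str) -> list[int]:
        return self.counts[self.row_labels.index(label)]


def _assign_bin(evalue: float, edges: Sequence[float]) -> int | None:
    """Bin index for an e-value; None means overflow (above the top edge).

    Bin i covers [edges[i+1], edges[i]); the final index is the underflow
    bin for values below the smallest edge (including exact 0).
    """
    if evalue >= edges[0]:
        return None
    if evalue < edges[-1]:
        return len(edges) - 1  # underflow / most-significant bin
    # binary search over strictly decreasing edges
    lo, hi = 0, len(edges) - 2
    while lo < hi:
        mid = (lo + hi) // 2
        if evalue < edges[mid + 1]:
            lo = mid + 1
        else:
            hi = mid
    return lo


def build_profile(
    hits: Iterable[BlastHit],
    bins: Sequence[float] | None = None,
    min_hits: int = 10,
    row_mode: str = "genus",
    group_map: TaxonGroupMap | None = None,
    row_order: Sequence[str] | None = None,
) -> ProfileMatrix:
    """Bin BLAST hits into a per-genus (or per-group) e-value profile.

    Every hit is counted (no per-ORF deduplication).  In ``custom-groups``
    mode each hit's species is mapped through ``group_map``; unmappable
    species are collected in an "unassigned" row with a warning.  Rows whose
    total is below ``min_hits`` are dropped (tracked in ``dropped_hits``);
    e-values at or above the top edge are tracked as ``overflow_hits``.
    """
    edges = list(bins) if bins is not None else default_bin_edges()
    if any(edges[i] <= edges[i + 1] for i in range(len(edges) - 1)):
        raise ValueError("bin edges must be strictly decreasing in e-value")
    if row_mode not in ("genus", "custom-groups"):
        raise ValueError(f"unknown row mode {row_mode!r}")
    if row_mode == "custom-groups" and group_map is None:
        raise ValueError("custom-groups mode requires a group map")

    n_bins = len(edges)  # includes underflow bin
    table: dict[str, list[int]] = {}
    overflow = 0
    for hit in hits:
        if row_mode == "genus":
            row = hit.genus
            if not row:
                raise ValueError(f"hit {hit.query!r} has an empty genus")
        else:
            if hit.species in group_map:
                row = group_map.group_of(hit.species)
            else:
                warnings.warn(
                    f"species {hit.species!r} not in group map; counted as"
                    " 'unassigned'",
                    stacklevel=2,
                )
                row = "unassigned"
        idx = _assign_bin(hit.evalue, edges)
        if idx is None:
            overflow += 1
            continue
        table.setdefault(row, [0] * n_bins)[idx] += 1

    kept: dict[str, list[int]] = {}
    dropped = 0
    for row, counts in table.items():
        if sum(counts) >= min_hits:
            kept[row] = counts
        else:
            dropped += sum(counts)

    if row_order is not None:
        order = [r for r in row_order if r in kept]
        order += sorted(r for r in kept if r not in order)
    else:
        order = sorted(kept)
    return ProfileMatrix(
        row_labels=order,
        bin_edges=edges,
        counts=[kept[r] for r in order],
        min_hits=min_hits,
        total_hits=sum(sum(c) for c in kept.values()),
        dropped_hits=dropped,
        overflow_hits=overflow,
    )


def render_profile(
    pm: ProfileMatrix,
    path: str | Path,
    scale: str = "log10(count+1)",
    image_path: str | Path | None = None,
) -> None:
    """Write the matrix as TSV (counts plus scaled values); optionally also
    render a raster heat map."""
    if scale not in ("log10(count+1)", "linear"):
        raise ValueError(f"unknown scale {scale!r}")

    def scaled(c: int) -> float:
        return math.log10(c + 1) if scale == "log10(count+1)" else float(c)

    lines = [
        "# profile matrix"
        f"\tmin_hits={pm.min_hits}\ttotal={pm.total_hits}"
        f"\tdropped={pm.dropped_hits}\toverflow={pm.overflow_hits}"
        f"\tscale={scale}"
        f"\tedges={','.join(format(e, '.6g') for e in pm.bin_edges)}",
        "#row\t" + "\t".join(pm.column_labels),
    ]
    for label, counts in zip(pm.row_labels, pm.counts):
        lines.append(label + "\t" + "\t".join(str(c) for c in counts))
    for label, counts in zip(pm.row_labels, pm.counts):
        lines.append(
            f"{label}(scaled)\t" + "\t".join(format(scaled(c), ".6g") for c in counts)
        )
    Path(path).write_text("\n".join(lines) + "\n", encoding="utf-8")

    if image_path is not None:
        import matplotlib

        matplotlib.use("Agg")
        import matplotlib.pyplot as plt
        import numpy as np

        data = np.array(
            [[scaled(c) for c in row] for row in pm.counts], dtype=float
        )
        fig, ax = plt.subplots(
            figsize=(max(4, pm.n_bins * 0.25), max(2, len(pm.row_labels) * 0.4))
        )
        ax.imshow(data, aspect="auto", cmap="viridis")
        ax.set_yticks(range(len(pm.row_labels)), pm.row_labels, fontsize=6)
        ax.set_xlabel("e-value range (significant to the right)")
        fig.tight_layout()
        fig.savefig(image_path, dpi=150)
        plt.close(fig)


def read_profile(path: str | Path) -> ProfileMatrix:
    """Re-read a matrix written by :func:`render_profile` (counts only)."""
    lines = Path(path).read_text(encoding="utf-8").splitlines()
    meta = dict(
        item.split("=", 1)
        for item in lines[0].split("\t")[1:]
        if "=" in item
    )
    edges = [float(x) for x in meta["edges"].split(",")]
    rows: list[str] = []
    counts: list[list[int]] = []
    for line in lines[2:]:
        if not line.strip():
            continue
        cells = line.split("\t")
        if cells[0].endswith("(scaled)"):
            continue
        rows.append(cells[0])
        counts.append([int(c) for c in cells[1:]])
    return ProfileMatrix(
        row_labels=rows,
        bin_edges=edges,
        counts=counts,
        min_hits=int(meta["min_hits"]),
        total_hits=int(meta["total"]),
        dropped_hits=int(meta["dropped"]),
        overflow_hits=int(meta["overflow"]),
    )
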