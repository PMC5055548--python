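"""Spatio-temporal patch extraction and normalization.

A spatio-temporal patch is an s x s image window followed through T
timepoints and vectorized to length m = s^2 * t.  Vectorization order is
fixed and versioned: timepoint-major, then row-major within each slice
(``patch[t, r, c]`` flattens with t slowest, c fastest).  Dictionaries are
only meaningful under one consistent ordering, so this order is part of the
on-disk contract.

Each patch y is centered and projected to the unit sphere,
``(y - mean(y)) / ||y - mean(y)||_2``; patches whose centered norm falls
below ``min_contrast`` are flat background and are discarded rather than
mapped to degenerate zero vectors.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass

import numpy as np
from numpy.lib.stride_tricks import sliding_window_view

from .phantom import SpatioTemporalVolume

VECTORIZATION_ORDER = "t-major/row-major/v1"


@dataclass
class PatchConfig:
    """Patch geometry: spatial side ``s`` (pixels), stride (default ``s``,
    i.e. non-overlapping tiling), timepoints consumed ``t`` and the
    flat-patch discard threshold ``min_contrast`` (FA units)."""

    s: int = 13
    stride: int | None = None
    t: int = 3
    min_contrast: float = 1e-6

    def __post_init__(self) -> None:
        if self.stride is None:
            self.stride = self.s
        if self.s < 2:
            raise ValueError("patch side s must be >= 2")
        if not 1 <= self.stride <= self.s:
            raise ValueError("stride must satisfy 1 <= stride <= s")
        if self.t < 1:
            raise ValueError("t must be >= 1")

    @property
    def m(self) -> int:
        """Patch vector length m = s^2 * t."""
        return self.s * self.s * self.t

    def replace(self, **kw) -> "PatchConfig":
        return dataclasses.replace(self, **kw)


@dataclass
class PatchMatrix:
    """Column-stacked normalized patches with per-column provenance.

    ``columns`` is m x N; ``subject_ids``, ``row_offsets``, ``col_offsets``
    recover each patch's origin; ``labels`` carries the subject class down
    to the patch level (None for unlabeled data).
    """

    columns: np.ndarray
    subject_ids: np.ndarray
    row_offsets: np.ndarray
    col_offsets: np.ndarray
    labels: np.ndarray | None = None
    s: int = 0
    t: int = 0

    @property
    def m(self) -> int:
        return self.columns.shape[0]

    @property
    def n_patches(self) -> int:
        return self.columns.shape[1]

    def for_subject(self, subject_id: str) -> np.ndarray:
        return self.columns[:, self.subject_ids == subject_id]

    @staticmethod
    def concatenate(blocks: list["PatchMatrix"]) -> "PatchMatrix":
        if not blocks:
            raise ValueError("no PatchMatrix blocks to concatenate")
        labels = None
        if all(b.labels is not None for b in blocks):
            labels = np.concatenate([b.labels for b in blocks])
        return PatchMatrix(
            columns=np.hstack([b.columns for b in blocks]),
            subject_ids=np.concatenate([b.subject_ids for b in blocks]),
            row_offsets=np.concatenate([b.row_offsets for b in blocks]),
            col_offsets=np.concatenate([b.col_offsets for b in blocks]),
            labels=labels,
            s=blocks[0].s,
            t=blocks[0].t,
        )

    def select(self, mask: np.ndarray) -> "PatchMatrix":
        return PatchMatrix(
            columns=self.columns[:, mask],
            subject_ids=self.subject_ids[mask],
            row_offsets=self.row_offsets[mask],
            col_offsets=self.col_offsets[mask],
            labels=None if self.labels is None else self.labels[mask],
            s=self.s,
            t=self.t,
        )


def normalize_patch(raw: np.ndarray, min_contrast: float = 1e-6) -> np.ndarray | None:
    """Center a raw patch vector and scale it to unit L2 norm.

    Returns None (the discard signal) when the centered norm is below
    ``min_contrast`` — a flat background patch carries no structure for
    sparse coding.  The output is invariant to affine intensity changes
    ``c*y + b`` with c > 0.
    """
    raw = np.asarray(raw, dtype=float)
    if not np.all(np.isfinite(raw)):
        raise ValueError("patch contains non-finite values")
    centered = raw - raw.mean()
    nrm = float(np.linalg.norm(centered))
    if nrm < min_contrast:
        return None
    return centered / nrm


def raw_patch_grid(values: np.ndarray, config: PatchConfig) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """All raw patch vectors of a stack on the stride grid.

    Returns (m x N raw columns, row offsets, col offsets); no
    normalization, no discarding.
    """
    h, w, T = values.shape
    s, stride, t = config.s, config.stride, config.t
    if h < s or w < s:
        raise ValueError(f"image {h}x{w} smaller than patch side s={s}")
    if T < t:
        raise ValueError(f"volume has {T} timepoints, patch config consumes t={t}")
    # windows: (h-s+1, w-s+1, t, s, s) -> stride subsample -> vectorize (t, s, s)
    win = sliding_window_view(values[:, :, :t], (s, s), axis=(0, 1))
    win = win[::stride, ::stride]                  # (nr, nc, t, s, s)
    nr, nc = win.shape[:2]
    cols = win.reshape(nr * nc, t * s * s).T       # t-major, then row-major
    rows = np.repeat(np.arange(nr) * stride, nc)
    colo = np.tile(np.arange(nc) * stride, nr)
    return np.ascontiguousarray(cols, dtype=float), rows, colo


def extract_patches(volume: SpatioTemporalVolume, config: PatchConfig) -> PatchMatrix:
    """Tile a subject's 2D+t stack into normalized patch columns.

    Patches tile the image on the stride grid (top-left anchored); flat
    patches are discarded.  The per-column index recovers each patch's
    origin exactly.
    """
    cols, rows, colo = raw_patch_grid(volume.values, config)
    m, n = cols.shape
    mean = cols.mean(axis=0, keepdims=True)
    centered = cols - mean
    nrm = np.linalg.norm(centered, axis=0)
    keep = nrm >= config.min_contrast
    normalized = centered[:, keep] / nrm[keep]
    labels = None
    if volume.label is not None:
        labels = np.full(keep.sum(), volume.label, dtype=object)
    return PatchMatrix(
        columns=normalized,
        subject_ids=np.full(keep.sum(), volume.subject_id, dtype=object),
        row_offsets=rows[keep],
        col_offsets=colo[keep],
        labels=labels,
        s=config.s,
        t=config.t,
    )


def extract_cohort_patches(volumes: list[SpatioTemporalVolume], config: PatchConfig) -> PatchMatrix:
    """Extract and concatenate normalized patches for a list of subjects."""
    return PatchMatrix.concatenate([extract_patches(v, config) for v in volumes])


def save_patches(pm: PatchMatrix, path) -> None:
    """Persist a patch matrix as an array archive with a sidecar index
    table (<path>.index.tsv: column, subject_id, row_offset, col_offset)."""
    from pathlib import Path

    path = Path(path)
    np.savez_compressed(path, columns=pm.columns, s=pm.s, t=pm.t,
                        order=VECTORIZATION_ORDER)
    rows = ["column\tsubject_id\trow_offset\tcol_offset\tlabel"]
    labels = pm.labels if pm.labels is not None else [""] * pm.n_patches
    for i in range(pm.n_patches):
        rows.append(f"{i}\t{pm.subject_ids[i]}\t{pm.row_offsets[i]}\t{pm.col_offsets[i]}\t{labels[i]}")
    path.with_suffix(path.suffix + ".index.tsv").write_text("\n".join(rows) + "\n")


def load_patches(path) -> PatchMatrix:
    """Load a patch matrix written by :func:`save_patches`."""
    from pathlib import Path

    path = Path(path)
    with np.load(path, allow_pickle=False) as npz:
        if str(npz["order"]) != VECTORIZATION_ORDER:
            raise ValueError(f"incompatible vectorization order {npz['order']!r}")
        columns = npz["columns"]
        s, t = int(npz["s"]), int(npz["t"])
    sids, rows, cols, labels = [], [], [], []
    with open(path.with_suffix(path.suffix + ".index.tsv")) as fh:
        fh.readline()
        for line in fh:
            _, sid, r, c, lab = line.rstrip("\n").split("\t")
            sids.append(sid); rows.append(int(r)); cols.append(int(c)); labels.append(lab)
    labels_arr = None if all(l == "" for l in labels) else np.asarray(labels, dtype=object)
    return PatchMatrix(
        columns=columns,
        subject_ids=np.asarray(sids, dtype=object),
        row_offsets=np.asarray(rows),
        col_offsets=np.asarray(cols),
        labels=labels_arr,
        s=s,
        t=t,
    )
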