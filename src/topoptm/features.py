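"""Vectorization of persistence barcodes into the 356-entry topological
feature vector.

Four blocks are concatenated, all computed from heavy-atom point clouds of
a 41-residue lysine-centered peptide window:

* TF1 (48) — whole-window Vietoris–Rips: death-time bin counts for
  dimensions 0/1/2, ranked 0-bar lengths, 0-bar length sum/mean, onset of
  the longest 1-bar, and barcode statistics of 1- and 2-bars.
* TF2 (30) — whole-window Alpha: barcode statistics of 1- and 2-bars.
* TF3 (240) — per flanking residue (40 of them, the center excluded), a
  6-entry summary of that residue's own VR barcode; dummy-X residues
  contribute zeros.
* TF4 (38) — the 5-residue local region: all-atom VR, carbon-only VR and
  a nitrogen-only 0-bar count (element-specific persistent homology).

Bins are half-open intervals (lo, hi] on death times.  Statistics are
max/min/mean/sum/population-std of births (BT), deaths (DT) and bar
lengths (BL), in that order; an empty bar set yields zeros.  Infinite
0-bars are excluded everywhere; bars still alive at the filtration cap
are treated as dying there (right-censoring, see :mod:`topoptm.ph`).
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .ph import Barcode, FiltrationSpec, PointCloud, element_filter, vr_barcodes, alpha_barcodes
from .structure_io import Structure, residue_heavy_atoms
from .windows import (
    LOCAL_FLANK,
    WINDOW_FLANK,
    PeptideWindow,
    SampleSet,
    window_point_cloud,
)

# death-time bin edges (Å) per dimension for the whole-window VR barcode
TF1_D0_EDGES = (1.2, 1.3, 1.4, 1.5, 1.6, 2.0)
TF1_D1_EDGES = (1.5, 2.7, 3.5, 4.5, 5.0, 6.7)
TF1_D2_EDGES = (2.4, 2.9, 5.5, 6.7)
# per-residue 0-bar bins
TF3_EDGES = (1.25, 1.5, 1.75)
# local-region bins: all-atom 0-bars, carbon-only 0-bars
TF4_ALL_EDGES = (1.2, 1.3, 1.4, 1.5, 1.6)
TF4_C_EDGES = (1.5, 2.0, 2.5, 3.0)
TF4_N_DEATH_MAX = 10.0

# filtration caps: smallest values leaving every binned feature uncensored
R_F_WINDOW = 7.0
R_F_RESIDUE = 6.0
R_F_LOCAL = 7.0
R_F_LOCAL_N = 12.0

TF1_LEN, TF2_LEN, TF3_LEN, TF4_LEN = 48, 30, 240, 38
TOTAL_LEN = TF1_LEN + TF2_LEN + TF3_LEN + TF4_LEN  # 356

BLOCK_SLICES = {
    "tf1": slice(0, 48),
    "tf2": slice(48, 78),
    "tf3": slice(78, 318),
    "tf4": slice(318, 356),
}

_STAT_NAMES = tuple(
    f"{q}_{s}" for q in ("bt", "dt", "bl") for s in ("max", "min", "mean", "sum", "std")
)


@dataclass(frozen=True)
class BinSpec:
    """Half-open death- (or birth-) time bins for one homology dimension."""

    edges: tuple[float, ...]
    dim: int
    quantity: str = "death"

    def __post_init__(self):
        object.__setattr__(self, "edges", tuple(float(e) for e in self.edges))
        if len(self.edges) < 2 or np.any(np.diff(self.edges) <= 0):
            raise ValueError("edges must be strictly increasing, length >= 2")
        if self.quantity not in ("death", "birth"):
            raise ValueError(f"bad quantity {self.quantity!r}")
        if self.dim not in (0, 1, 2):
            raise ValueError("dim must be 0, 1 or 2")


@dataclass(frozen=True)
class FeatureVector:
    values: np.ndarray
    names: tuple[str, ...] = field(default_factory=tuple)

    def __post_init__(self):
        vals = np.asarray(self.values, dtype=float).reshape(-1)
        object.__setattr__(self, "values", vals)
        if vals.shape[0] != TOTAL_LEN:
            raise ValueError(f"expected {TOTAL_LEN} features, got {vals.shape[0]}")
        if not np.all(np.isfinite(vals)):
            raise ValueError("feature values must be finite")

    def block(self, name: str) -> np.ndarray:
        return self.values[BLOCK_SLICES[name]]


def bin_counts(barcode: Barcode, spec: BinSpec) -> np.ndarray:
    """Count finite bars of the given dimension whose death (or birth)
    time falls in each half-open bin (lo, hi]."""
    vals = barcode.deaths(spec.dim) if spec.quantity == "death" else barcode.births(spec.dim)
    edges = np.asarray(spec.edges)
    out = np.zeros(len(edges) - 1, dtype=float)
    for i in range(len(edges) - 1):
        out[i] = np.count_nonzero((vals > edges[i]) & (vals <= edges[i + 1]))
    return out


def barcode_stats(barcode: Barcode, dim: int) -> np.ndarray:
    """The 15 barcode statistics of one dimension's finite bars:
    [max, min, mean, sum, std] applied to BTs, then DTs, then BLs.
    Standard deviation is population-style; no bars gives 15 zeros."""
    births, deaths = barcode.births(dim), barcode.deaths(dim)
    if births.size == 0:
        return np.zeros(15)
    out = []
    for v in (births, deaths, deaths - births):
        out.extend([v.max(), v.min(), v.mean(), v.sum(), v.std()])
    return np.array(out)


def _ranked_lengths(barcode: Barcode, dim: int) -> list:
    """Finite bars sorted by length desc; ties by earlier birth, then input
    order."""
    bars = barcode.finite_bars(dim)
    return sorted(
        range(len(bars)),
        key=lambda i: (-bars[i].length, bars[i].birth, i),
    ), bars


def tf1(window_cloud: PointCloud) -> np.ndarray:
    """48 whole-window Vietoris–Rips features."""
    if len(window_cloud) == 0:
        raise ValueError("empty window cloud")
    bc = vr_barcodes(window_cloud, FiltrationSpec("vr", r_f=R_F_WINDOW, max_hom_dim=2))
    parts = [
        bin_counts(bc, BinSpec(TF1_D0_EDGES, dim=0)),
        bin_counts(bc, BinSpec(TF1_D1_EDGES, dim=1)),
        bin_counts(bc, BinSpec(TF1_D2_EDGES, dim=2)),
    ]
    order0, bars0 = _ranked_lengths(bc, 0)
    second = bars0[order0[1]].length if len(order0) > 1 else 0.0
    third = bars0[order0[2]].length if len(order0) > 2 else 0.0
    lens0 = bc.lengths(0)
    parts.append(np.array([
        second,
        third,
        lens0.sum() if lens0.size else 0.0,
        lens0.mean() if lens0.size else 0.0,
    ]))
    order1, bars1 = _ranked_lengths(bc, 1)
    parts.append(np.array([bars1[order1[0]].birth if order1 else 0.0]))
    parts.append(barcode_stats(bc, 1))
    parts.append(barcode_stats(bc, 2))
    vec = np.concatenate(parts)
    assert vec.shape[0] == TF1_LEN
    return vec


def tf2(window_cloud: PointCloud) -> np.ndarray:
    """30 whole-window Alpha features: 1- and 2-bar statistics."""
    if len(window_cloud) == 0:
        raise ValueError("empty window cloud")
    bc = alpha_barcodes(window_cloud, FiltrationSpec("alpha", r_f=R_F_WINDOW, max_hom_dim=2))
    vec = np.concatenate([barcode_stats(bc, 1), barcode_stats(bc, 2)])
    assert vec.shape[0] == TF2_LEN
    return vec


def _residue_block(structure: Structure, residue_number: int) -> np.ndarray:
    atoms = residue_heavy_atoms(structure, residue_number)
    if not atoms:
        return np.zeros(6)
    cloud = PointCloud(
        np.array([a.coords for a in atoms]),
        tuple(a.element.upper() for a in atoms),
    )
    bc = vr_barcodes(cloud, FiltrationSpec("vr", r_f=R_F_RESIDUE, max_hom_dim=2))
    counts = bin_counts(bc, BinSpec(TF3_EDGES, dim=0))
    n_zero_bars = len(bc.finite_bars(0)) + bc.n_infinite(0)
    return np.array([
        counts[0],
        counts[1],
        float(n_zero_bars),
        bc.lengths(0).sum(),
        bc.lengths(1).sum() if bc.lengths(1).size else 0.0,
        bc.lengths(2).sum() if bc.lengths(2).size else 0.0,
    ])


def tf3(structure: Structure, window: PeptideWindow) -> np.ndarray:
    """240 per-flanking-residue features (6 per residue, center excluded).

    Residues padded with the dummy code X contribute six zeros.
    """
    _check_window(structure, window)
    blocks = []
    for off in list(range(-WINDOW_FLANK, 0)) + list(range(1, WINDOW_FLANK + 1)):
        pos = window.center + off
        letter = window.peptide[WINDOW_FLANK + off]
        if letter == "X" or not 1 <= pos <= len(structure):
            blocks.append(np.zeros(6))
        else:
            blocks.append(_residue_block(structure, pos))
    vec = np.concatenate(blocks)
    assert vec.shape[0] == TF3_LEN
    return vec


def tf4(structure: Structure, window: PeptideWindow) -> np.ndarray:
    """38 local-region features (residues center−2 .. center+2).

    All-atom VR bins + 1-bar statistics; carbon-only VR bins + 1-bar
    statistics; nitrogen-only count of 0-bars dying before 10 Å.
    """
    _check_window(structure, window)
    cloud = window_point_cloud(structure, window.center, LOCAL_FLANK)

    bc_all = vr_barcodes(cloud, FiltrationSpec("vr", r_f=R_F_LOCAL, max_hom_dim=1))
    parts = [
        bin_counts(bc_all, BinSpec(TF4_ALL_EDGES, dim=0)),
        barcode_stats(bc_all, 1),
    ]

    c_cloud = element_filter(cloud, {"C"})
    if len(c_cloud):
        bc_c = vr_barcodes(c_cloud, FiltrationSpec("vr", r_f=R_F_LOCAL, max_hom_dim=1))
        parts += [bin_counts(bc_c, BinSpec(TF4_C_EDGES, dim=0)), barcode_stats(bc_c, 1)]
    else:
        parts += [np.zeros(3), np.zeros(15)]

    n_cloud = element_filter(cloud, {"N"})
    if len(n_cloud):
        bc_n = vr_barcodes(n_cloud, FiltrationSpec("vr", r_f=R_F_LOCAL_N, max_hom_dim=0))
        n_feat = float(np.count_nonzero(bc_n.deaths(0) < TF4_N_DEATH_MAX))
    else:
        n_feat = 0.0
    parts.append(np.array([n_feat]))
    vec = np.concatenate(parts)
    assert vec.shape[0] == TF4_LEN
    return vec


def _check_window(structure: Structure, window: PeptideWindow) -> None:
    L = len(structure)
    if not 1 <= window.center <= L:
        raise ValueError(
            f"window center {window.center} outside structure 1..{L}"
        )
    if structure.sequence[window.center - 1] != "K":
        raise ValueError("window center is not lysine in the structure")


def featurize(structure: Structure, window: PeptideWindow) -> FeatureVector:
    """The full 356-entry feature vector TF1‖TF2‖TF3‖TF4 for one window."""
    cloud = window_point_cloud(structure, window.center, WINDOW_FLANK)
    values = np.concatenate([
        tf1(cloud),
        tf2(cloud),
        tf3(structure, window),
        tf4(structure, window),
    ])
    return FeatureVector(values, feature_names())


def _bin_names(prefix: str, edges: Sequence[float], dim: int) -> list[str]:
    return [
        f"{prefix}_d{dim}_count_({edges[i]},{edges[i + 1]}]"
        for i in range(len(edges) - 1)
    ]


def feature_names() -> tuple[str, ...]:
    """Stable per-feature identifiers, one per vector entry."""
    names: list[str] = []
    names += _bin_names("tf1", TF1_D0_EDGES, 0)
    names += _bin_names("tf1", TF1_D1_EDGES, 1)
    names += _bin_names("tf1", TF1_D2_EDGES, 2)
    names += ["tf1_d0_bl_2nd_longest", "tf1_d0_bl_3rd_longest",
              "tf1_d0_bl_sum", "tf1_d0_bl_mean", "tf1_d1_longest_birth"]
    names += [f"tf1_d1_{s}" for s in _STAT_NAMES]
    names += [f"tf1_d2_{s}" for s in _STAT_NAMES]
    names += [f"tf2_d1_{s}" for s in _STAT_NAMES]
    names += [f"tf2_d2_{s}" for s in _STAT_NAMES]
    for off in list(range(-WINDOW_FLANK, 0)) + list(range(1, WINDOW_FLANK + 1)):
        tag = f"tf3_res{off:+d}"
        names += [
            f"{tag}_d0_count_(1.25,1.5]",
            f"{tag}_d0_count_(1.5,1.75]",
            f"{tag}_n_0bars",
            f"{tag}_d0_bl_sum",
            f"{tag}_d1_bl_sum",
            f"{tag}_d2_bl_sum",
        ]
    names += _bin_names("tf4_all", TF4_ALL_EDGES, 0)
    names += [f"tf4_all_d1_{s}" for s in _STAT_NAMES]
    names += _bin_names("tf4_C", TF4_C_EDGES, 0)
    names += [f"tf4_C_d1_{s}" for s in _STAT_NAMES]
    names += ["tf4_N_d0_count_lt10"]
    assert len(names) == TOTAL_LEN
    return tuple(names)


# ---------------------------------------------------------------------------
# feature matrices
# ---------------------------------------------------------------------------

def feature_matrix(
    structures: Mapping[str, Structure], samples: SampleSet
) -> pd.DataFrame:
    """One row per window: protein_id, position, label, f_0001..f_0356."""
    rows = []
    for w in samples.windows:
        st = structures[w.protein_id]
        fv = featurize(st, w)
        rows.append([w.protein_id, w.center, w.label, *fv.values])
    cols = ["protein_id", "position", "label"] + [
        f"f_{i + 1:04d}" for i in range(TOTAL_LEN)
    ]
    return pd.DataFrame(rows, columns=cols)


def write_feature_matrix(df: pd.DataFrame, path: str | Path) -> None:
    """TSV matrix plus a sidecar JSON mapping column id -> feature name."""
    path = Path(path)
    df.to_csv(path, sep="\t", index=False)
    mapping = {
        f"f_{i + 1:04d}": name for i, name in enumerate(feature_names())
    }
    path.with_suffix(path.suffix + ".names.json").write_text(
        json.dumps(mapping, indent=1)
    )
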