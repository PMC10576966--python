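"""Lysine-centered peptide windows and redundancy filtering.

A candidate site is encoded as a 41-residue peptide: the central lysine K
plus 20 residues upstream and 20 downstream, padded with the dummy code X
where the window runs past a sequence terminus.  Redundancy between
windows is measured as positionwise identity over the fixed 41 positions
(windows are pre-aligned by their centers), and a greedy keep-first pass
drops any window more than 40% identical to one already kept.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping

import numpy as np
import pandas as pd

from .ph import PointCloud
from .structure_io import Structure, heavy_atoms

WINDOW_FLANK = 20
WINDOW_LEN = 2 * WINDOW_FLANK + 1  # 41
#: flank of the local region used by the TF4 block
LOCAL_FLANK = 2


@dataclass(frozen=True)
class PeptideWindow:
    protein_id: str
    center: int  # 1-based position of the central lysine
    peptide: str
    label: str = "unlabeled"  # positive | negative | unlabeled

    def __post_init__(self):
        if len(self.peptide) != WINDOW_LEN:
            raise ValueError(
                f"peptide must have {WINDOW_LEN} residues, got {len(self.peptide)}"
            )
        if self.peptide[WINDOW_FLANK] != "K":
            raise ValueError("window center must be lysine (K)")
        core = self.peptide.strip("X")
        if "X" in core:
            raise ValueError("dummy code X may only pad the window ends")
        if self.label not in ("positive", "negative", "unlabeled"):
            raise ValueError(f"bad label {self.label!r}")


@dataclass(frozen=True)
class SampleSet:
    windows: tuple[PeptideWindow, ...]
    provenance: str = ""

    def __post_init__(self):
        object.__setattr__(self, "windows", tuple(self.windows))
        keys = [(w.protein_id, w.center) for w in self.windows]
        if len(set(keys)) != len(keys):
            raise ValueError("duplicate (protein_id, center) in sample set")

    def __len__(self) -> int:
        return len(self.windows)

    def by_label(self, label: str) -> list[PeptideWindow]:
        return [w for w in self.windows if w.label == label]


def extract_window(
    sequence: str,
    position: int,
    protein_id: str = "",
    label: str = "unlabeled",
) -> PeptideWindow:
    """41-mer around a 1-based lysine position, X-padded at the termini."""
    L = len(sequence)
    if not 1 <= position <= L:
        raise ValueError(f"position {position} outside 1..{L}")
    if sequence[position - 1] != "K":
        raise ValueError(
            f"position {position} of {protein_id or 'sequence'} is "
            f"{sequence[position - 1]!r}, not K"
        )
    chars = []
    for p in range(position - WINDOW_FLANK, position + WINDOW_FLANK + 1):
        chars.append(sequence[p - 1] if 1 <= p <= L else "X")
    return PeptideWindow(protein_id, position, "".join(chars), label)


def pairwise_identity(a: PeptideWindow, b: PeptideWindow) -> float:
    """Fraction of the 41 positions at which the peptides agree (X matches X)."""
    return sum(x == y for x, y in zip(a.peptide, b.peptide)) / WINDOW_LEN


def redundancy_filter(samples: SampleSet, threshold: float = 0.40) -> SampleSet:
    """Greedy de-redundancy: keep a window iff its identity with every
    already-kept window is ≤ threshold.

    Positive and negative windows are pooled (classes are mixed before
    comparing, then the survivors keep their labels); the pass runs in a
    fixed documented order — (protein_id, center) — so the result is
    deterministic.
    """
    if not 0 < threshold < 1:
        raise ValueError("threshold must be in (0, 1)")
    ordered = sorted(samples.windows, key=lambda w: (w.protein_id, w.center))
    kept: list[PeptideWindow] = []
    kept_arr: list[np.ndarray] = []
    for w in ordered:
        arr = np.frombuffer(w.peptide.encode(), dtype=np.uint8)
        if all(
            int((arr == other).sum()) <= threshold * WINDOW_LEN
            for other in kept_arr
        ):
            kept.append(w)
            kept_arr.append(arr)
    return SampleSet(tuple(kept), provenance=samples.provenance)


def window_point_cloud(
    structure: Structure, center: int, flank: int = WINDOW_FLANK
) -> PointCloud:
    """Heavy-atom cloud of residues center−flank .. center+flank.

    Residues outside [1, L] (window padding) contribute no atoms.
    """
    L = len(structure)
    if not 1 <= center <= L:
        raise ValueError(f"center {center} outside 1..{L}")
    if structure.sequence[center - 1] != "K":
        raise ValueError(
            f"residue {center} of {structure.protein_id} is "
            f"{structure.sequence[center - 1]!r}, not K"
        )
    lo, hi = max(1, center - flank), min(L, center + flank)
    atoms = [a for a in heavy_atoms(structure) if lo <= a.residue_number <= hi]
    if not atoms:
        raise ValueError(f"no heavy atoms in residues {lo}..{hi}")
    return PointCloud(
        np.array([a.coords for a in atoms]),
        tuple(a.element.upper() for a in atoms),
    )


# ---------------------------------------------------------------------------
# annotation table -> sample sets
# ---------------------------------------------------------------------------

def read_annotations(path: str | Path) -> pd.DataFrame:
    """Tab-separated site table with header ``protein_id  position  label``."""
    df = pd.read_csv(path, sep="\t", dtype={"protein_id": str})
    required = {"protein_id", "position", "label"}
    if not required.issubset(df.columns):
        raise ValueError(f"annotation table must have columns {sorted(required)}")
    return df


def build_samples(
    sequences: Mapping[str, str],
    annotations: pd.DataFrame | Iterable[tuple[str, int, str]],
    negatives_from_unannotated: bool = True,
    provenance: str = "",
) -> SampleSet:
    """Windows for every annotated site, plus (optionally) a negative window
    for every non-annotated lysine of the annotated proteins."""
    if isinstance(annotations, pd.DataFrame):
        rows = list(
            annotations[["protein_id", "position", "label"]].itertuples(index=False)
        )
    else:
        rows = list(annotations)

    windows: list[PeptideWindow] = []
    annotated: dict[str, set[int]] = {}
    for pid, pos, label in rows:
        label = str(label)
        label = {"1": "positive", "0": "negative"}.get(label, label)
        seq = sequences.get(pid)
        if seq is None:
            raise KeyError(f"no sequence for annotated protein {pid!r}")
        windows.append(extract_window(seq, int(pos), pid, label))
        annotated.setdefault(pid, set()).add(int(pos))

    if negatives_from_unannotated:
        for pid in sorted(annotated):
            seq = sequences[pid]
            for pos in range(1, len(seq) + 1):
                if seq[pos - 1] == "K" and pos not in annotated[pid]:
                    windows.append(extract_window(seq, pos, pid, "negative"))
    return SampleSet(tuple(windows), provenance=provenance)


def write_samples(samples: SampleSet, path: str | Path) -> None:
    df = pd.DataFrame(
        [(w.protein_id, w.center, w.peptide, w.label) for w in samples.windows],
        columns=["protein_id", "position", "peptide", "label"],
    )
    df.to_csv(path, sep="\t", index=False)


def read_samples(path: str | Path, provenance: str = "") -> SampleSet:
    df = pd.read_csv(path, sep="\t", dtype={"protein_id": str})
    windows = tuple(
        PeptideWindow(r.protein_id, int(r.position), r.peptide, r.label)
        for r in df.itertuples(index=False)
    )
    return SampleSet(windows, provenance=provenance)
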