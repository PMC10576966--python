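"""Deterministic synthetic peptide structures for pipeline testing.

Residues are placed along an idealized backbone trace — an α-helix-like
spiral (``compact``: radius 2.29 Å, rise 1.5 Å, ~100°/residue) or a
straight strand (``extended``) — with consecutive CA atoms 3.8 Å apart.
Each residue carries its full complement of heavy atoms built from an
idealized template: backbone N/CA/C/O with N–CA 1.46 Å, CA–C 1.52 Å,
C–O 1.23 Å and an inter-residue peptide bond C–N of 1.33 Å; side chains
grown atom-by-atom with element-typed bond lengths (C–C 1.53, C–N 1.47,
C–O 1.43, C–S 1.55 Å) and planar rings for His/Phe/Tyr/Trp.  Every bonded
distance therefore falls in the 1.2–1.6 Å covalent band that the
dimension-0 feature bins probe.

The geometry is a fixture, not a physical model: no torsional preferences,
no ring closure for proline, no sterics beyond what the construction
gives.  Gaussian coordinate noise (``noise_sd``) and the residue sequence
are drawn from a seeded generator, so identical specs give bit-identical
structures.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd

from .structure_io import AA1_TO_3, AtomRecord, Structure, write_structure
from .windows import SampleSet, extract_window

CA_SPACING = 3.8
# cos/sin of the ~34° tilt that makes the peptide bond C(i)-N(i+1) 1.33 Å:
# 3.8 - (1.52 + 1.46) cosθ = 1.33
_CT = (CA_SPACING - 1.33) / (1.52 + 1.46)
_ST = float(np.sqrt(1.0 - _CT ** 2))
_BOND = {"CC": 1.53, "CN": 1.47, "CO": 1.43, "CS": 1.55}

# side-chain growth directions in the local (ex, ey, ez) residue frame:
# the chain zigzags away from the backbone (-ey) alternating in ez,
# branches split in ±ex
_DIR_A = np.array([0.0, -0.820, 0.573])
_DIR_B = np.array([0.0, -0.820, -0.573])
_DIR_BR1 = np.array([0.701, -0.601, 0.383])
_DIR_BR2 = np.array([-0.701, -0.601, 0.383])

#: simple linear side chains: names in bonding order from CB
_CHAINS = {
    "ALA": ["CB"],
    "CYS": ["CB", "SG"],
    "SER": ["CB", "OG"],
    "MET": ["CB", "CG", "SD", "CE"],
    "LYS": ["CB", "CG", "CD", "CE", "NZ"],
    "PRO": ["CB", "CG", "CD"],
    "GLY": [],
}
#: chain + two branch atoms on the last chain atom
_BRANCHED = {
    "THR": (["CB"], ["OG1", "CG2"]),
    "VAL": (["CB"], ["CG1", "CG2"]),
    "LEU": (["CB", "CG"], ["CD1", "CD2"]),
    "ASP": (["CB", "CG"], ["OD1", "OD2"]),
    "ASN": (["CB", "CG"], ["OD1", "ND2"]),
    "GLU": (["CB", "CG", "CD"], ["OE1", "OE2"]),
    "GLN": (["CB", "CG", "CD"], ["OE1", "NE2"]),
    "ARG": (["CB", "CG", "CD", "NE", "CZ"], ["NH1", "NH2"]),
}
_ILE_EXTRA = "CD1"  # continues from CG1

_PENT = {"HIS": ["CG", "ND1", "CE1", "NE2", "CD2"],
         "TRP": ["CG", "CD1", "NE1", "CE2", "CD2"]}
_HEX = {"PHE": ["CG", "CD1", "CE1", "CZ", "CE2", "CD2"],
        "TYR": ["CG", "CD1", "CE1", "CZ", "CE2", "CD2"]}
_TRP_HEX = ["CD2", "CE2", "CZ2", "CH2", "CZ3", "CE3"]  # fused on CD2-CE2

_RING_SIDE = {"pent": 1.37, "hex": 1.39}


@dataclass(frozen=True)
class FixtureSpec:
    sequence: str
    conformation: str = "compact"  # compact | extended
    noise_sd: float = 0.0
    seed: int = 0

    def __post_init__(self):
        bad = sorted(set(self.sequence) - set(AA1_TO_3))
        if bad:
            raise ValueError(f"invalid residue letters: {bad}")
        if self.conformation not in ("compact", "extended"):
            raise ValueError(f"unknown conformation {self.conformation!r}")
        if self.noise_sd < 0:
            raise ValueError("noise_sd must be >= 0")


def _unit(v: np.ndarray) -> np.ndarray:
    return v / np.linalg.norm(v)


def _bond(parent_elem: str, child_elem: str) -> float:
    pair = "".join(sorted((parent_elem, child_elem)))
    pair = {"CC": "CC", "CN": "CN", "CO": "CO", "CS": "CS"}.get(pair, "CC")
    return _BOND[pair]


def _ring(attach: np.ndarray, a: np.ndarray, b: np.ndarray, n: int, side: float):
    """Regular n-gon in the plane (a, b); vertex 0 at ``attach``, the ring
    extending along ``a``."""
    R = side / (2.0 * np.sin(np.pi / n))
    center = attach + R * a
    angles = 2.0 * np.pi * np.arange(n) / n
    return center[None, :] - R * np.outer(np.cos(angles), a) \
        + R * np.outer(np.sin(angles), b)


def _side_chain(res: str, ex, ey, ez) -> list[tuple[str, np.ndarray]]:
    """Local side-chain coordinates (relative to CA) for one residue."""
    out: list[tuple[str, np.ndarray]] = []
    frame = np.stack([ex, ey, ez])

    def glob(v):
        return v @ frame

    def grow(names, start, parent_elem="C"):
        pos = start.copy()
        pe = parent_elem  # CA is carbon
        for k, name in enumerate(names):
            d = _DIR_A if k % 2 == 0 else _DIR_B
            pos = pos + _bond(pe, name[0]) * _unit(d)
            out.append((name, glob(pos)))
            pe = name[0]
        return pos

    if res in _CHAINS:
        grow(_CHAINS[res], np.zeros(3))
    elif res in _BRANCHED:
        chain, branch = _BRANCHED[res]
        tip = grow(chain, np.zeros(3))
        parent_elem = chain[-1][0]
        for name, d in zip(branch, (_DIR_BR1, _DIR_BR2)):
            out.append((name, glob(tip + _bond(parent_elem, name[0]) * _unit(d))))
    elif res == "ILE":
        tip = grow(["CB"], np.zeros(3))
        g1 = tip + _BOND["CC"] * _unit(_DIR_BR1)
        g2 = tip + _BOND["CC"] * _unit(_DIR_BR2)
        out.append(("CG1", glob(g1)))
        out.append(("CG2", glob(g2)))
        out.append((_ILE_EXTRA, glob(g1 + _BOND["CC"] * _unit(_DIR_B))))
    elif res in ("HIS", "PHE", "TYR", "TRP"):
        tip = grow(["CB"], np.zeros(3))
        cg = tip + 1.51 * _unit(_DIR_B)
        ring_a = _unit(_DIR_B)
        # ring plane ⊥ the backbone direction so neighbors can't reach it
        ring_b = _unit(np.cross(ring_a, np.array([1.0, 0.0, 0.0])))
        if res in _PENT:
            names = _PENT[res]
            verts = _ring(cg, ring_a, ring_b, 5, _RING_SIDE["pent"])
        else:
            names = _HEX[res]
            verts = _ring(cg, ring_a, ring_b, 6, _RING_SIDE["hex"])
        ring = dict(zip(names, verts))
        for name in names:
            out.append((name, glob(ring[name])))
        if res == "TYR":
            center = cg + (_RING_SIDE["hex"] / (2 * np.sin(np.pi / 6))) * ring_a
            oh = ring["CZ"] + _BOND["CO"] * _unit(ring["CZ"] - center)
            out.append(("OH", glob(oh)))
        if res == "TRP":
            p1, p2 = ring["CD2"], ring["CE2"]
            s = float(np.linalg.norm(p2 - p1))
            pent_center = verts.mean(axis=0)
            mid = 0.5 * (p1 + p2)
            nhat = _unit(mid - pent_center)
            hex_center = mid + (s * np.sqrt(3) / 2.0) * nhat
            e1 = _unit(p1 - hex_center)
            e2v = p2 - hex_center
            e2 = _unit(e2v - np.dot(e2v, e1) * e1)
            Rh = float(np.linalg.norm(p1 - hex_center))
            for k, name in enumerate(_TRP_HEX):
                if name in ("CD2", "CE2"):
                    continue
                th = np.pi * k / 3.0
                v = hex_center + Rh * (np.cos(th) * e1 + np.sin(th) * e2)
                out.append((name, glob(v)))
    else:  # pragma: no cover
        raise ValueError(f"no side-chain template for {res}")
    return out


def _trace(n: int, conformation: str) -> np.ndarray:
    if conformation == "extended":
        return np.column_stack(
            [CA_SPACING * np.arange(n), np.zeros(n), np.zeros(n)]
        )
    omega = np.deg2rad(100.0)
    rise = 1.5
    radius = np.sqrt((CA_SPACING ** 2 - rise ** 2) / (2.0 * (1.0 - np.cos(omega))))
    i = np.arange(n)
    return np.column_stack(
        [radius * np.cos(i * omega), radius * np.sin(i * omega), rise * i]
    )


def _backbone(ca: np.ndarray, conformation: str):
    """Place N, C and O for every residue along the CA trace.

    Both C(i) and N(i+1) are tilted off segment i by 34° in a common plane,
    which fixes the peptide bond C(i)–N(i+1) at 1.33 Å for *any* azimuth of
    that plane around the segment axis.  The azimuth is chosen per segment
    (deterministic grid search) to keep C(i) clear of the same residue's N
    and of the side-chain attachment point — necessary because the local
    frame rotates ~100° per residue along the helical trace.
    """
    n = len(ca)
    tangents = np.zeros_like(ca)
    tangents[:-1] = ca[1:] - ca[:-1]
    tangents[-1] = tangents[-2]
    tangents = tangents / np.linalg.norm(tangents, axis=1, keepdims=True)

    # reference perpendicular: toward the helix axis, or +z for a strand
    perps = np.zeros_like(ca)
    for i in range(n):
        if conformation == "extended":
            v = np.array([0.0, 0.0, 1.0])
        else:
            v = -np.array([ca[i, 0], ca[i, 1], 0.0])
        v = v - np.dot(v, tangents[i]) * tangents[i]
        perps[i] = _unit(v)

    cb_dir = _unit(_DIR_A)

    def cb_of(i):
        ez = np.cross(tangents[i], perps[i])
        return ca[i] + 1.53 * (cb_dir @ np.stack([tangents[i], perps[i], ez]))

    npos = np.zeros_like(ca)
    cpos = np.zeros_like(ca)
    thetas = np.linspace(0.0, 2.0 * np.pi, 24, endpoint=False)
    for i in range(n - 1):
        t = tangents[i]
        a = perps[i]
        b = np.cross(t, a)
        if i == 0:
            npos[0] = ca[0] + 1.46 * (-_CT * t + _ST * a)

        def place(theta):
            w = np.cos(theta) * a + np.sin(theta) * b
            c_i = ca[i] + 1.52 * (_CT * t + _ST * w)
            n_next = ca[i + 1] + 1.46 * (-_CT * t + _ST * w)
            return c_i, n_next

        def clearance(theta):
            c_i, n_next = place(theta)
            return min(
                np.linalg.norm(c_i - npos[i]),
                np.linalg.norm(c_i - cb_of(i)),
                np.linalg.norm(n_next - cb_of(i + 1)),
            )

        best = max(thetas, key=clearance)
        cpos[i], npos[i + 1] = place(best)
    # last residue: carbonyl reuses the final segment's frame
    t, a = tangents[-1], perps[-1]
    b = np.cross(t, a)

    def last_clearance(theta):
        w = np.cos(theta) * a + np.sin(theta) * b
        c = ca[-1] + 1.52 * (_CT * t + _ST * w)
        return min(np.linalg.norm(c - npos[-1]), np.linalg.norm(c - cb_of(n - 1)))

    w = max(thetas, key=last_clearance)
    cpos[-1] = ca[-1] + 1.52 * (_CT * t + _ST * (np.cos(w) * a + np.sin(w) * b))

    opos = np.zeros_like(ca)
    phis = np.linspace(0.0, 2.0 * np.pi, 24, endpoint=False)
    for i in range(n):
        t = tangents[i]
        a = perps[i]
        b = np.cross(t, a)
        nearby = [npos[i], ca[i], cb_of(i)]
        if i + 1 < n:
            nearby += [npos[i + 1], ca[i + 1], cb_of(i + 1)]

        def o_at(phi):
            d = _unit(-0.2 * t + 0.96 * (np.cos(phi) * b + np.sin(phi) * a))
            return cpos[i] + 1.23 * d

        opos[i] = max(
            (o_at(phi) for phi in phis),
            key=lambda p: min(np.linalg.norm(p - q) for q in nearby),
        )
    return tangents, perps, npos, cpos, opos


def synth_structure(spec: FixtureSpec) -> Structure:
    """Build a synthetic all-heavy-atom peptide structure for a spec.

    Deterministic: the same spec yields bit-identical coordinates.
    """
    seq = spec.sequence
    n = len(seq)
    if n < 2:
        raise ValueError("need at least 2 residues")
    ca = _trace(n, spec.conformation)
    tangents, perps, npos_all, cpos_all, opos_all = _backbone(ca, spec.conformation)

    rng = np.random.default_rng(spec.seed)
    atoms: list[AtomRecord] = []
    for i, letter in enumerate(seq):
        res3 = AA1_TO_3[letter]
        t_out, u_out = tangents[i], perps[i]
        npos, cpos, opos = npos_all[i], cpos_all[i], opos_all[i]
        ex, ey = t_out, u_out
        ez = np.cross(ex, ey)
        placed = [("N", npos), ("CA", ca[i]), ("C", cpos), ("O", opos)]
        placed += [(nm, ca[i] + off) for nm, off in _side_chain(res3, ex, ey, ez)]
        for name, pos in placed:
            noisy = pos + rng.normal(0.0, spec.noise_sd, 3) if spec.noise_sd else pos
            atoms.append(
                AtomRecord(
                    element=name[0],
                    atom_name=name,
                    residue_number=i + 1,
                    residue_name=res3,
                    coords=noisy,
                )
            )
    return Structure(protein_id=f"synthetic-{spec.conformation}", sequence=seq,
                     atoms=tuple(atoms))


# ---------------------------------------------------------------------------
# labeled datasets
# ---------------------------------------------------------------------------

_AA20 = "ACDEFGHIKLMNPQRSTVWY"


def _random_window_sequence(rng: np.random.Generator) -> str:
    left = "".join(rng.choice(list(_AA20), 20))
    right = "".join(rng.choice(list(_AA20), 20))
    return left + "K" + right


def synth_dataset(
    n_pos: int,
    n_neg: int,
    seed: int = 0,
    noise_sd: float = 0.05,
) -> tuple[SampleSet, dict[str, Structure]]:
    """A miniature labeled dataset whose classes differ in conformation.

    Positives are compact (helical) 41-residue peptides, negatives are
    extended; flanking sequences are random in both classes, so the class
    signal is geometric, not compositional.
    """
    if n_pos < 1 or n_neg < 1:
        raise ValueError("need at least one sample per class")
    rng = np.random.default_rng(seed)
    windows = []
    structures: dict[str, Structure] = {}
    for k in range(n_pos + n_neg):
        positive = k < n_pos
        pid = f"{'POS' if positive else 'NEG'}{k:04d}"
        seq = _random_window_sequence(rng)
        spec = FixtureSpec(
            sequence=seq,
            conformation="compact" if positive else "extended",
            noise_sd=noise_sd,
            seed=int(rng.integers(0, 2**31 - 1)),
        )
        st = synth_structure(spec)
        st = Structure(protein_id=pid, sequence=st.sequence, atoms=st.atoms)
        structures[pid] = st
        windows.append(
            extract_window(seq, 21, pid, "positive" if positive else "negative")
        )
    return SampleSet(tuple(windows), provenance=f"synthetic(seed={seed})"), structures


def simulate(
    outdir: str | Path,
    n_pos: int = 10,
    n_neg: int = 10,
    seed: int = 0,
    noise_sd: float = 0.05,
) -> Path:
    """Write a complete miniature dataset directory: one PDB per peptide
    plus the site-annotation TSV consumed by the windows module."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    samples, structures = synth_dataset(n_pos, n_neg, seed=seed, noise_sd=noise_sd)
    rows = []
    for w in samples.windows:
        write_structure(structures[w.protein_id], outdir / f"{w.protein_id}.pdb")
        rows.append((w.protein_id, w.center, w.label))
    pd.DataFrame(rows, columns=["protein_id", "position", "label"]).to_csv(
        outdir / "sites.tsv", sep="\t", index=False
    )
    return outdir
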