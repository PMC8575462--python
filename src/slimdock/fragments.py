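"""Peptide-fragment mining from coordinate files.

Given a set of structures and a short sequence pattern with ``x``
wildcards (e.g. ``xHPRVx`` or ``xEPxxxPRx``), this module excises every
contiguous, backbone-complete fragment matching the pattern, computes
per-residue backbone torsions (phi, psi, omega), clusters conformers under
a max-circular-torsion metric with DBSCAN, selects a reference conformer
(best crystallographic resolution in the largest cluster), and screens
fragments by the Glu-carboxylate-to-Arg-guanidinium end-to-end span that
determines whether a peptide can bridge the phosphatase active site and
the B55α groove anchor.  A small survey utility measures the shortest
Mn(2+)-to-phosphate-oxygen distance per metal ion, the geometry used to
position a phosphomimetic in the active site.

Conventions adopted where the underlying procedure is underdetermined:
selenomethionine (MSE) reads as M and other nonstandard residues reject a
fragment; chain contiguity requires consecutive CA-CA distances <= 4.5 Å;
the Glu-Arg span is the minimum over the <= 4 OE x NH atom pairs; the
survey's dispersion is a population (n-denominator) standard deviation.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Sequence

import gemmi
import numpy as np
from sklearn.cluster import DBSCAN

from .geometry import circular_difference, dihedral

__all__ = [
    "Fragment",
    "DihedralProfile",
    "ClusterConfig",
    "SurveyResult",
    "extract_fragments",
    "backbone_dihedrals",
    "dihedral_distance",
    "pairwise_dihedral_distances",
    "cluster_fragments",
    "select_reference",
    "endpoint_span",
    "filter_by_span",
    "mn_phosphate_survey",
]

BACKBONE_ATOMS = ("N", "CA", "C", "O")
CA_BREAK_CUTOFF = 4.5  # Å between consecutive CA atoms

_PHOSPHATE_OXYGENS = {
    "O1", "O2", "O3", "O4",
    "O1P", "O2P", "O3P", "O4P",
    "OP1", "OP2", "OP3", "OP4",
}


@dataclass
class Fragment:
    """A contiguous peptide excised from a structure.

    ``backbone`` is (n, 4, 3) in N, CA, C, O order; ``cb`` is (n, 3) with
    NaN rows where no CB exists (glycine).  ``marked_atoms`` carries the
    role-tagged side-chain coordinates the placement pipeline measures:
    ``GLU_OE`` (OE1/OE2 of the pattern Glu) and ``ARG_NH`` (NH1/NH2 of the
    pattern Arg), each a (k, 3) array.
    """

    structure_id: str
    chain_id: str
    start_seqid: str
    end_seqid: str
    sequence: str
    core_start: int  # index into the fragment of the first non-wildcard position
    core_end: int    # index one past the last non-wildcard position
    backbone: np.ndarray
    cb: np.ndarray
    residue_numbers: list[int] = field(default_factory=list)
    marked_atoms: dict[str, np.ndarray] = field(default_factory=dict)
    resolution: float | None = None

    @property
    def id(self) -> str:
        return f"{self.structure_id}:{self.chain_id}:{self.start_seqid}-{self.end_seqid}"

    def __len__(self) -> int:
        return len(self.sequence)

    def transformed(self, tform) -> "Fragment":
        """Return a copy with all coordinates moved by a rigid transform."""
        return Fragment(
            structure_id=self.structure_id,
            chain_id=self.chain_id,
            start_seqid=self.start_seqid,
            end_seqid=self.end_seqid,
            sequence=self.sequence,
            core_start=self.core_start,
            core_end=self.core_end,
            backbone=tform.apply(self.backbone.reshape(-1, 3)).reshape(self.backbone.shape),
            cb=tform.apply(self.cb),
            residue_numbers=list(self.residue_numbers),
            marked_atoms={k: tform.apply(v) for k, v in self.marked_atoms.items()},
            resolution=self.resolution,
        )


@dataclass(frozen=True)
class DihedralProfile:
    """Per-residue phi/psi/omega in degrees, NaN where undefined.

    phi is undefined at the first residue; psi and omega at the last
    (omega(i) couples residue i to i+1).
    """

    phi: np.ndarray
    psi: np.ndarray
    omega: np.ndarray
    core_start: int = 0
    core_end: int | None = None

    def angles(self, core_only: bool = False) -> np.ndarray:
        """(n, 3) stack of phi, psi, omega, optionally restricted to the core."""
        stack = np.column_stack([self.phi, self.psi, self.omega])
        if core_only:
            end = self.core_end if self.core_end is not None else len(self.phi)
            stack = stack[self.core_start : end]
        return stack


@dataclass(frozen=True)
class ClusterConfig:
    eps: float = 60.0     # degrees; neighborhood radius on the torsion metric
    min_pts: int = 5

    def __post_init__(self):
        if self.eps <= 0:
            raise ValueError("eps must be positive")
        if self.min_pts < 1:
            raise ValueError("min_pts must be >= 1")


# ---------------------------------------------------------------------------
# extraction


def _parse_simple_pattern(pattern_text: str) -> list[str | None]:
    """'xHPRVx' -> [None, 'H', 'P', 'R', 'V', None]; classes via [..]."""
    out: list[str | None] = []
    i = 0
    while i < len(pattern_text):
        ch = pattern_text[i]
        if ch == "x":
            out.append(None)
            i += 1
        elif ch == "[":
            j = pattern_text.index("]", i)
            out.append(pattern_text[i + 1 : j])
            i = j + 1
        elif ch.isalpha() and ch.isupper():
            out.append(ch)
            i += 1
        else:
            raise ValueError(f"bad character {ch!r} in fragment pattern")
    if all(p is None for p in out):
        raise ValueError("pattern has no fixed positions")
    return out


def _residue_one_letter(res: gemmi.Residue) -> str | None:
    if res.name == "MSE":
        return "M"
    info = gemmi.find_tabulated_residue(res.name)
    if info is None or not info.is_amino_acid():
        return None
    code = info.one_letter_code.upper()
    return code if code in "ACDEFGHIKLMNPQRSTVWY" else None


def _structure_resolution(st: gemmi.Structure) -> float | None:
    res = st.resolution
    return float(res) if res and res > 0 else None


def extract_fragments(
    structures: Sequence[gemmi.Structure], pattern_text: str
) -> list[Fragment]:
    """Excise every fragment matching a fixed-length wildcard pattern.

    A match must be contiguous (consecutive CA-CA <= 4.5 Å), carry all four
    backbone atoms at every position, and contain no nonstandard residues
    (MSE is read as Met).  Wildcard flanks are part of the pattern, so a
    motif at a chain terminus without its flank is simply not a match.
    """
    pattern = _parse_simple_pattern(pattern_text)
    core_idx = [i for i, p in enumerate(pattern) if p is not None]
    core_start, core_end = core_idx[0], core_idx[-1] + 1
    n = len(pattern)
    fragments: list[Fragment] = []
    for st in structures:
        resolution = _structure_resolution(st)
        if not len(st):
            continue
        model = st[0]
        for chain in model:
            residues = [r for r in chain if _residue_one_letter(r) or r.name == "MSE"
                        or (gemmi.find_tabulated_residue(r.name) is not None
                            and gemmi.find_tabulated_residue(r.name).is_amino_acid())]
            letters = [_residue_one_letter(r) for r in residues]
            for start in range(0, len(residues) - n + 1):
                window = residues[start : start + n]
                win_letters = letters[start : start + n]
                if any(l is None for l in win_letters):
                    continue
                if any(
                    p is not None and win_letters[i] not in p
                    for i, p in enumerate(pattern)
                ):
                    continue
                frag = _build_fragment(
                    st.name, chain.name, window, "".join(win_letters),
                    core_start, core_end, pattern, resolution,
                )
                if frag is not None:
                    fragments.append(frag)
    return fragments


def _build_fragment(
    structure_id, chain_id, window, seq, core_start, core_end, pattern, resolution
) -> Fragment | None:
    n = len(window)
    backbone = np.full((n, 4, 3), np.nan)
    cb = np.full((n, 3), np.nan)
    for i, res in enumerate(window):
        for j, name in enumerate(BACKBONE_ATOMS):
            atom = res.find_atom(name, "*")
            if atom is None:
                return None  # incomplete backbone rejects the fragment
            backbone[i, j] = [atom.pos.x, atom.pos.y, atom.pos.z]
        atom = res.find_atom("CB", "*")
        if atom is not None:
            cb[i] = [atom.pos.x, atom.pos.y, atom.pos.z]
    ca = backbone[:, 1]
    if np.any(np.linalg.norm(np.diff(ca, axis=0), axis=1) > CA_BREAK_CUTOFF):
        return None  # chain break
    marked: dict[str, np.ndarray] = {}
    for role, resname, atom_names in (
        ("GLU_OE", "E", ("OE1", "OE2")),
        ("ARG_NH", "R", ("NH1", "NH2")),
    ):
        idx = _role_position(pattern, seq, resname)
        if idx is None:
            continue
        coords = []
        for name in atom_names:
            atom = window[idx].find_atom(name, "*")
            if atom is not None:
                coords.append([atom.pos.x, atom.pos.y, atom.pos.z])
        if coords:
            marked[role] = np.array(coords)
    numbers = [r.seqid.num for r in window]
    return Fragment(
        structure_id=structure_id,
        chain_id=chain_id,
        start_seqid=str(window[0].seqid),
        end_seqid=str(window[-1].seqid),
        sequence=seq,
        core_start=core_start,
        core_end=core_end,
        backbone=backbone,
        cb=cb,
        residue_numbers=numbers,
        marked_atoms=marked,
        resolution=resolution,
    )


def _role_position(pattern, seq, letter) -> int | None:
    """Prefer the pattern position fixed to ``letter``; else its first occurrence."""
    for i, p in enumerate(pattern):
        if p is not None and p == letter:
            return i
    for i, ch in enumerate(seq):
        if ch == letter:
            return i
    return None


# ---------------------------------------------------------------------------
# torsions


def backbone_dihedrals(fragment: Fragment) -> DihedralProfile:
    """Standard IUPAC backbone torsions; NaN at undefined terminal positions."""
    bb = fragment.backbone
    n = len(fragment)
    phi = np.full(n, np.nan)
    psi = np.full(n, np.nan)
    omega = np.full(n, np.nan)
    for i in range(n):
        N, CA, C = bb[i, 0], bb[i, 1], bb[i, 2]
        if i > 0:
            phi[i] = dihedral(bb[i - 1, 2], N, CA, C)
        if i < n - 1:
            psi[i] = dihedral(N, CA, C, bb[i + 1, 0])
            omega[i] = dihedral(CA, C, bb[i + 1, 0], bb[i + 1, 1])
    for name, arr in (("phi", phi), ("psi", psi), ("omega", omega)):
        interior = arr[1:-1]
        if np.any(np.isnan(interior)):
            warnings.warn(
                f"{fragment.id}: degenerate geometry left {name} undefined",
                stacklevel=2,
            )
    return DihedralProfile(phi, psi, omega, fragment.core_start, fragment.core_end)


def dihedral_distance(
    a: DihedralProfile, b: DihedralProfile, core_only: bool = True
) -> float:
    """Max over residue positions and angle types of the circular difference.

    Positions where either side is undefined (NaN) are skipped; if nothing
    is comparable the distance is undefined and an error is raised.
    """
    A = a.angles(core_only)
    B = b.angles(core_only)
    if A.shape != B.shape:
        raise ValueError("profiles have different (core) lengths")
    mask = ~(np.isnan(A) | np.isnan(B))
    if not mask.any():
        raise ValueError("no comparable angle pair between profiles")
    return float(np.max(circular_difference(A[mask], B[mask])))


def pairwise_dihedral_distances(
    profiles: Sequence[DihedralProfile], core_only: bool = True
) -> np.ndarray:
    n = len(profiles)
    D = np.zeros((n, n))
    for i in range(n):
        for j in range(i + 1, n):
            D[i, j] = D[j, i] = dihedral_distance(profiles[i], profiles[j], core_only)
    return D


# ---------------------------------------------------------------------------
# clustering and reference selection


def cluster_fragments(
    fragments: Sequence[Fragment],
    profiles: Sequence[DihedralProfile],
    config: ClusterConfig,
    core_only: bool = True,
) -> np.ndarray:
    """DBSCAN labels under the max-circular-torsion metric; -1 marks noise."""
    if len(fragments) == 0:
        raise ValueError("no fragments to cluster")
    if len(fragments) != len(profiles):
        raise ValueError("fragments and profiles differ in length")
    D = pairwise_dihedral_distances(profiles, core_only)
    labels = DBSCAN(
        eps=config.eps, min_samples=config.min_pts, metric="precomputed"
    ).fit_predict(D)
    return labels


def _resolution_key(frag: Fragment):
    # absent resolution (e.g. NMR ensembles) ranks last
    return (frag.resolution is None, frag.resolution if frag.resolution is not None else 0.0, frag.id)


def select_reference(labels: np.ndarray, fragments: Sequence[Fragment]) -> Fragment:
    """Best-resolution member of the largest cluster.

    Equal-sized clusters are broken toward the one whose best member has the
    lower resolution; remaining ties fall back to lexicographic fragment id.
    """
    labels = np.asarray(labels)
    clusters: dict[int, list[Fragment]] = {}
    for lab, frag in zip(labels, fragments):
        if lab != -1:
            clusters.setdefault(int(lab), []).append(frag)
    if not clusters:
        raise ValueError("all fragments are noise; no cluster to select from")
    best_members = {
        lab: min(members, key=_resolution_key) for lab, members in clusters.items()
    }
    chosen = min(
        clusters,
        key=lambda lab: (-len(clusters[lab]),) + _resolution_key(best_members[lab]),
    )
    return best_members[chosen]


# ---------------------------------------------------------------------------
# end-to-end span


def endpoint_span(fragment: Fragment, mode: str = "min") -> float:
    """Glu(OE1/OE2) to Arg(NH1/NH2) distance over the <= 4 atom pairs."""
    try:
        oe = fragment.marked_atoms["GLU_OE"]
        nh = fragment.marked_atoms["ARG_NH"]
    except KeyError as exc:
        raise ValueError(f"{fragment.id}: missing marked anchor atoms") from exc
    d = np.linalg.norm(oe[:, None, :] - nh[None, :, :], axis=-1).ravel()
    if mode == "min":
        return float(d.min())
    if mode == "max":
        return float(d.max())
    if mode == "mean":
        return float(d.mean())
    raise ValueError(f"unknown span mode {mode!r}")


def filter_by_span(
    fragments: Sequence[Fragment], min_span: float = 20.0, mode: str = "min"
) -> list[Fragment]:
    """Retain fragments whose end-to-end span is >= min_span (inclusive)."""
    return [f for f in fragments if endpoint_span(f, mode) >= min_span]


# ---------------------------------------------------------------------------
# Mn-phosphate survey


@dataclass(frozen=True)
class SurveyResult:
    """Shortest Mn-O(phosphate) distance per metal ion, with aggregates.

    ``sd`` is the population standard deviation (n denominator).
    """

    per_ion: list[tuple[str, float]]
    skipped: list[str]

    @property
    def distances(self) -> np.ndarray:
        return np.array([d for _, d in self.per_ion])

    @property
    def mean(self) -> float:
        return float(self.distances.mean())

    @property
    def sd(self) -> float:
        return float(self.distances.std(ddof=0))

    def to_dict(self) -> dict:
        return {
            "per_ion": [{"ion": k, "min_distance_A": d} for k, d in self.per_ion],
            "mean_A": self.mean,
            "sd_A": self.sd,
            "sd_convention": "population (n denominator)",
            "skipped_structures": self.skipped,
        }


def _phosphate_oxygens(st: gemmi.Structure) -> np.ndarray:
    coords = []
    for chain in st[0]:
        for res in chain:
            if res.name in ("PO4", "PI"):
                for atom in res:
                    if atom.element.name == "O":
                        coords.append([atom.pos.x, atom.pos.y, atom.pos.z])
            else:
                for atom in res:
                    if atom.name in _PHOSPHATE_OXYGENS and atom.element.name == "O":
                        coords.append([atom.pos.x, atom.pos.y, atom.pos.z])
    return np.array(coords) if coords else np.empty((0, 3))


def mn_phosphate_survey(structures: Sequence[gemmi.Structure]) -> SurveyResult:
    """Per Mn(2+) ion, the shortest distance to any phosphate oxygen."""
    per_ion: list[tuple[str, float]] = []
    skipped: list[str] = []
    for st in structures:
        mn = []
        for chain in st[0]:
            for res in chain:
                for atom in res:
                    if atom.element.name == "Mn":
                        mn.append([atom.pos.x, atom.pos.y, atom.pos.z])
        oxy = _phosphate_oxygens(st)
        if not mn or oxy.size == 0:
            warnings.warn(
                f"{st.name}: no Mn/phosphate pair; skipped from survey",
                stacklevel=2,
            )
            skipped.append(st.name)
            continue
        for i, pos in enumerate(np.array(mn)):
            d = float(np.linalg.norm(oxy - pos, axis=1).min())
            per_ion.append((f"{st.name}:MN{i + 1}", d))
    if not per_ion:
        raise ValueError("no structure contributed a Mn-phosphate distance")
    return SurveyResult(per_ion, skipped)
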