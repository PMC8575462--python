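"""Synthetic-data generators with machine-readable ground truth.

Every input class the analysis pipelines consume can be generated here
under a seed, with the ground truth (planted motif positions, conformer
cluster labels, scene geometry) recorded alongside:

* :func:`gen_proteome` -- random proteomes with SLiM instances planted at a
  known per-protein rate;
* :func:`gen_interactor_sets` -- interactor subsets sampled with a
  controlled enrichment factor for motif-positive proteins;
* :func:`build_peptide` / :func:`gen_conformer_library` -- peptide chains
  constructed from backbone torsions by internal-coordinate (NeRF)
  placement, optionally grouped into dihedral clusters with wrapped-Gaussian
  angular noise;
* :func:`gen_anchor_scene` -- mock two-fragment anchor scenes (metal pair,
  Asp carboxylate, Glu/Arg anchor atoms) with an exact requested span;
* :func:`build_mock_phosphatase` -- a minimal di-metal catalytic site with
  coordinating residues, an optional phosphomimetic Glu, and an optional
  regulatory-subunit Asp anchor, for exercising the assembly pipeline.

Generators are pure functions of (parameters, seed): the same call twice
produces byte-identical output.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict
from typing import Sequence

import gemmi
import numpy as np

from .geometry import place_atom, wrap_angle
from .motif import AMINO_ACIDS, MotifPattern, ProteinRecord, Fixed, ResidueClass, Wildcard, Gap, scan_sequence

__all__ = [
    "SyntheticTruth",
    "BuilderGeometry",
    "gen_proteome",
    "gen_interactor_sets",
    "build_peptide",
    "gen_conformer_library",
    "gen_anchor_scene",
    "build_mock_phosphatase",
    "HUMAN_FREQUENCIES",
]

# approximate Swiss-Prot amino-acid frequencies, renormalised
HUMAN_FREQUENCIES = {
    "A": 0.0826, "R": 0.0553, "N": 0.0406, "D": 0.0546, "C": 0.0137,
    "Q": 0.0393, "E": 0.0672, "G": 0.0708, "H": 0.0227, "I": 0.0591,
    "L": 0.0965, "K": 0.0580, "M": 0.0241, "F": 0.0386, "P": 0.0474,
    "S": 0.0665, "T": 0.0536, "W": 0.0110, "Y": 0.0292, "V": 0.0685,
}


@dataclass
class SyntheticTruth:
    """Ground-truth record emitted by every generator."""

    generator: str
    seed: int
    parameters: dict
    records: dict = field(default_factory=dict)

    def to_json(self, **kwargs) -> str:
        def _default(o):
            if isinstance(o, np.ndarray):
                return o.tolist()
            if isinstance(o, (np.integer,)):
                return int(o)
            if isinstance(o, (np.floating,)):
                return float(o)
            raise TypeError(f"not JSON-serializable: {type(o)}")

        return json.dumps(asdict(self), default=_default, sort_keys=True, **kwargs)


# ---------------------------------------------------------------------------
# proteomes with planted motifs


def _normalised_frequencies(residue_frequencies) -> tuple[list[str], np.ndarray]:
    if residue_frequencies is None:
        letters = list(AMINO_ACIDS)
        probs = np.full(len(letters), 1.0 / len(letters))
    elif residue_frequencies == "human":
        letters = list(HUMAN_FREQUENCIES)
        probs = np.array(list(HUMAN_FREQUENCIES.values()))
        probs = probs / probs.sum()
    else:
        letters = list(residue_frequencies)
        probs = np.array([residue_frequencies[l] for l in letters], float)
        if abs(probs.sum() - 1.0) > 1e-6:
            raise ValueError("residue frequencies must sum to 1")
        probs = probs / probs.sum()
    return letters, probs


def sample_motif_instance(
    pattern: MotifPattern, rng: np.random.Generator, letters, probs
) -> tuple[str, int, int]:
    """Draw one string from the pattern language (gap length uniform).

    Returns (instance, phospho_offset, anchor_offset), offsets 0-based.
    """
    parts: list[str] = []
    offsets = {}
    pos = 0
    for i, el in enumerate(pattern.elements):
        offsets[i] = pos
        if isinstance(el, Fixed):
            parts.append(el.letter)
            pos += 1
        elif isinstance(el, ResidueClass):
            parts.append(el.letters[rng.integers(len(el.letters))])
            pos += 1
        elif isinstance(el, Wildcard):
            parts.append(letters[rng.choice(len(letters), p=probs)])
            pos += 1
        elif isinstance(el, Gap):
            n = int(rng.integers(el.min_len, el.max_len + 1))
            parts.append("".join(letters[j] for j in rng.choice(len(letters), size=n, p=probs)))
            pos += n
    return "".join(parts), offsets[pattern.phospho_element_index], offsets[pattern.anchor_element_index]


def gen_proteome(
    n_proteins: int,
    pattern: MotifPattern,
    plant_rate: float,
    seed: int,
    length_range: tuple[int, int] = (150, 600),
    residue_frequencies=None,
    record_scan: bool = True,
) -> tuple[list[ProteinRecord], SyntheticTruth]:
    """Random proteome with motif instances planted at a known rate.

    Each protein independently receives one planted instance with
    probability ``plant_rate``; the instance overwrites a stretch of the
    background sequence at a uniformly chosen offset.  The truth record
    lists every plant (protein id, 1-based phospho/anchor positions) and,
    when ``record_scan`` is set, the scan-detected hits that are *not*
    plants (chance background hits).
    """
    if not 0.0 <= plant_rate <= 1.0:
        raise ValueError("plant_rate must be in [0, 1]")
    letters, probs = _normalised_frequencies(residue_frequencies)
    if plant_rate > 0:
        for el in pattern.elements:
            if isinstance(el, Fixed) and el.letter not in letters:
                raise ValueError("pattern unsatisfiable over the restricted alphabet")
            if isinstance(el, ResidueClass) and not set(el.letters) & set(letters):
                raise ValueError("pattern unsatisfiable over the restricted alphabet")
    rng = np.random.default_rng(seed)
    records: list[ProteinRecord] = []
    plants: list[dict] = []
    lo, hi = length_range
    for i in range(n_proteins):
        pid = f"SYN{i:05d}"
        length = int(rng.integers(lo, hi + 1))
        seq = "".join(letters[j] for j in rng.choice(len(letters), size=length, p=probs))
        if rng.random() < plant_rate:
            inst, ph_off, an_off = sample_motif_instance(pattern, rng, letters, probs)
            if len(inst) <= length:
                start = int(rng.integers(0, length - len(inst) + 1))
                seq = seq[:start] + inst + seq[start + len(inst):]
                plants.append(
                    {
                        "protein_id": pid,
                        "start": start + 1,
                        "phospho_pos": start + ph_off + 1,
                        "anchor_pos": start + an_off + 1,
                        "instance": inst,
                    }
                )
        records.append(ProteinRecord(id=pid, sequence=seq, description=pid))
    truth = SyntheticTruth(
        generator="gen_proteome",
        seed=seed,
        parameters={
            "n_proteins": n_proteins,
            "pattern": pattern.source_text,
            "plant_rate": plant_rate,
            "length_range": list(length_range),
            "residue_frequencies": "uniform" if residue_frequencies is None
            else residue_frequencies if isinstance(residue_frequencies, str) else "custom",
        },
        records={"plants": plants},
    )
    if record_scan:
        planted_keys = {
            (p["protein_id"], p["phospho_pos"], p["anchor_pos"]) for p in plants
        }
        background = []
        positive_ids = set()
        for rec in records:
            for hit in scan_sequence(pattern, rec):
                positive_ids.add(rec.id)
                key = (hit.protein_id, hit.phospho_pos, hit.anchor_pos)
                if key not in planted_keys:
                    background.append(
                        {
                            "protein_id": hit.protein_id,
                            "phospho_pos": hit.phospho_pos,
                            "anchor_pos": hit.anchor_pos,
                        }
                    )
        truth.records["background_hits"] = background
        truth.records["positive_ids"] = sorted(positive_ids)
        truth.records["all_ids"] = [r.id for r in records]
    return records, truth


def gen_interactor_sets(
    truth: SyntheticTruth,
    enrichment_factor: float,
    set_size: int,
    seed: int,
) -> tuple[list[str], SyntheticTruth]:
    """Sample an interactor set enriched for motif-positive proteins.

    Sampling is without replacement with weight ``enrichment_factor`` for
    motif-positive proteins and 1 for negatives (Efraimidis-Spirakis
    weighted reservoir keys, so the draw is an exact weighted sample and a
    pure function of the seed).  Factor 1 reduces to the hypergeometric
    null; factor ``inf`` takes positives first.
    """
    if enrichment_factor < 0:
        raise ValueError("enrichment factor must be >= 0")
    all_ids: list[str] = truth.records["all_ids"]
    positives = set(truth.records["positive_ids"])
    if set_size > len(all_ids):
        raise ValueError("set_size exceeds proteome size")
    n_neg = len(all_ids) - len(positives)
    if enrichment_factor == 0 and set_size > n_neg:
        raise ValueError("factor 0 with set_size larger than the negative pool")
    rng = np.random.default_rng(seed)
    u = rng.random(len(all_ids))
    keys = []
    for i, pid in enumerate(all_ids):
        w = enrichment_factor if pid in positives else 1.0
        if w == 0:
            key = -np.inf
        elif np.isinf(w):
            key = np.inf
        else:
            key = np.log(u[i]) / w  # log of u^(1/w); larger is better
        keys.append((key, u[i], pid))
    keys.sort(key=lambda t: (-t[0], t[1]))
    chosen = sorted(pid for _, _, pid in keys[:set_size])
    out_truth = SyntheticTruth(
        generator="gen_interactor_sets",
        seed=seed,
        parameters={"enrichment_factor": enrichment_factor, "set_size": set_size},
        records={
            "target_ids": chosen,
            "n_target_positive": sum(pid in positives for pid in chosen),
        },
    )
    return chosen, out_truth


# ---------------------------------------------------------------------------
# peptide construction from internal coordinates


@dataclass(frozen=True)
class BuilderGeometry:
    """Ideal backbone stereochemistry used by the chain builder (Å, degrees)."""

    bond_n_ca: float = 1.458
    bond_ca_c: float = 1.525
    bond_c_n: float = 1.329
    bond_c_o: float = 1.231
    bond_ca_cb: float = 1.530
    angle_n_ca_c: float = 111.2
    angle_ca_c_n: float = 116.2
    angle_c_n_ca: float = 121.7
    angle_ca_c_o: float = 120.5
    angle_n_ca_cb: float = 110.5
    torsion_c_n_ca_cb: float = -122.6  # improper fixing CB handedness

    def __post_init__(self):
        for name in ("bond_n_ca", "bond_ca_c", "bond_c_n", "bond_c_o", "bond_ca_cb"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")
        for name in ("angle_n_ca_c", "angle_ca_c_n", "angle_c_n_ca", "angle_ca_c_o", "angle_n_ca_cb"):
            if not 0.0 < getattr(self, name) < 180.0:
                raise ValueError(f"{name} must lie in (0, 180)")


_THREE = {
    "A": "ALA", "R": "ARG", "N": "ASN", "D": "ASP", "C": "CYS",
    "Q": "GLN", "E": "GLU", "G": "GLY", "H": "HIS", "I": "ILE",
    "L": "LEU", "K": "LYS", "M": "MET", "F": "PHE", "P": "PRO",
    "S": "SER", "T": "THR", "W": "TRP", "Y": "TYR", "V": "VAL",
}

# fixed all-anti side-chain stub torsions for the two anchor residues;
# the terminal branch splits the carboxylate / guanidinium plane
_GLU_STUB = [
    ("CG", "C", 1.52, 114.0, 180.0, ("N", "CA", "CB")),
    ("CD", "C", 1.52, 114.0, 180.0, ("CA", "CB", "CG")),
    ("OE1", "O", 1.25, 118.0, 0.0, ("CB", "CG", "CD")),
    ("OE2", "O", 1.25, 118.0, 180.0, ("CB", "CG", "CD")),
]
_ARG_STUB = [
    ("CG", "C", 1.52, 114.0, 180.0, ("N", "CA", "CB")),
    ("CD", "C", 1.52, 112.0, 180.0, ("CA", "CB", "CG")),
    ("NE", "N", 1.46, 112.0, 180.0, ("CB", "CG", "CD")),
    ("CZ", "C", 1.33, 124.0, 180.0, ("CG", "CD", "NE")),
    ("NH1", "N", 1.33, 120.0, 0.0, ("CD", "NE", "CZ")),
    ("NH2", "N", 1.33, 120.0, 180.0, ("CD", "NE", "CZ")),
]


def backbone_coordinates(
    dihedrals: np.ndarray, geometry: BuilderGeometry = BuilderGeometry()
) -> np.ndarray:
    """Backbone N/CA/C positions for a chain with the given torsions.

    ``dihedrals`` is (n, 3) of per-residue (phi, psi, omega) in degrees;
    phi of the first residue and psi/omega of the last are ignored (NaN is
    accepted there).
    """
    dih = np.atleast_2d(np.asarray(dihedrals, float))
    n = dih.shape[0]
    g = geometry
    coords = np.zeros((n, 3, 3))  # N, CA, C
    coords[0, 0] = [0.0, 0.0, 0.0]
    coords[0, 1] = [g.bond_n_ca, 0.0, 0.0]
    theta = np.radians(g.angle_n_ca_c)
    coords[0, 2] = coords[0, 1] + g.bond_ca_c * np.array(
        [-np.cos(theta), np.sin(theta), 0.0]
    )
    for i in range(1, n):
        psi_prev, omega_prev = dih[i - 1, 1], dih[i - 1, 2]
        if np.isnan(psi_prev) or np.isnan(omega_prev):
            raise ValueError(f"psi/omega of residue {i - 1} required to extend chain")
        Np = place_atom(
            coords[i - 1, 0], coords[i - 1, 1], coords[i - 1, 2],
            g.bond_c_n, g.angle_ca_c_n, psi_prev,
        )
        CAp = place_atom(
            coords[i - 1, 1], coords[i - 1, 2], Np,
            g.bond_n_ca, g.angle_c_n_ca, omega_prev,
        )
        phi = dih[i, 0]
        if np.isnan(phi):
            raise ValueError(f"phi of residue {i} required to extend chain")
        Cp = place_atom(coords[i - 1, 2], Np, CAp, g.bond_ca_c, g.angle_n_ca_c, phi)
        coords[i] = [Np, CAp, Cp]
    return coords


def build_peptide(
    dihedrals: np.ndarray,
    sequence: str,
    geometry: BuilderGeometry = BuilderGeometry(),
    chain_id: str = "A",
    name: str = "synthetic",
    resolution: float | None = None,
) -> gemmi.Structure:
    """Construct a peptide structure from per-residue backbone torsions.

    The backbone is placed sequentially by internal coordinates; carbonyl O
    and CB are added from ideal geometry; Glu and Arg residues receive
    full side-chain stubs ending in the OE1/OE2 and NH1/NH2 atoms the
    placement pipeline measures.  The result is a standard one-chain
    ``gemmi.Structure`` that round-trips through a PDB file.
    """
    dih = np.atleast_2d(np.asarray(dihedrals, float))
    if dih.shape[0] != len(sequence):
        raise ValueError("sequence length must equal the number of dihedral rows")
    g = geometry
    bb = backbone_coordinates(dih, g)
    st = gemmi.Structure()
    st.name = name
    if resolution is not None:
        st.resolution = resolution
    model = gemmi.Model("1")
    chain = gemmi.Chain(chain_id)
    n = len(sequence)
    for i, letter in enumerate(sequence):
        res = gemmi.Residue()
        res.name = _THREE[letter.upper()]
        res.seqid = gemmi.SeqId(i + 1, " ")
        atoms: list[tuple[str, str, np.ndarray]] = [
            ("N", "N", bb[i, 0]), ("CA", "C", bb[i, 1]), ("C", "C", bb[i, 2]),
        ]
        psi_eff = dih[i, 1] if i < n - 1 and not np.isnan(dih[i, 1]) else 180.0
        O = place_atom(bb[i, 0], bb[i, 1], bb[i, 2], g.bond_c_o, g.angle_ca_c_o, psi_eff + 180.0)
        atoms.append(("O", "O", O))
        placed = {"N": bb[i, 0], "CA": bb[i, 1], "C": bb[i, 2], "O": O}
        if letter.upper() != "G":
            CB = place_atom(bb[i, 2], bb[i, 0], bb[i, 1], g.bond_ca_cb,
                            g.angle_n_ca_cb, g.torsion_c_n_ca_cb)
            atoms.append(("CB", "C", CB))
            placed["CB"] = CB
            stub = _GLU_STUB if letter.upper() == "E" else _ARG_STUB if letter.upper() == "R" else []
            for aname, elem, bond, angle, torsion, refs in stub:
                pos = place_atom(placed[refs[0]], placed[refs[1]], placed[refs[2]],
                                 bond, angle, torsion)
                placed[aname] = pos
                atoms.append((aname, elem, pos))
        for aname, elem, pos in atoms:
            atom = gemmi.Atom()
            atom.name = aname
            atom.element = gemmi.Element(elem)
            atom.pos = gemmi.Position(*pos)
            atom.occ = 1.0
            res.add_atom(atom)
        chain.add_residue(res)
    model.add_chain(chain)
    st.add_model(model)
    st.setup_entities()
    return st


def _random_rotation(rng: np.random.Generator) -> np.ndarray:
    """Uniform random rotation matrix (via a random quaternion)."""
    q = rng.normal(size=4)
    q /= np.linalg.norm(q)
    w, x, y, z = q
    return np.array(
        [
            [1 - 2 * (y * y + z * z), 2 * (x * y - w * z), 2 * (x * z + w * y)],
            [2 * (x * y + w * z), 1 - 2 * (x * x + z * z), 2 * (y * z - w * x)],
            [2 * (x * z - w * y), 2 * (y * z + w * x), 1 - 2 * (x * x + y * y)],
        ]
    )


def _transform_structure(st: gemmi.Structure, R: np.ndarray, t: np.ndarray) -> None:
    for model in st:
        for chain in model:
            for res in chain:
                for atom in res:
                    p = np.array([atom.pos.x, atom.pos.y, atom.pos.z])
                    p = R @ p + t
                    atom.pos = gemmi.Position(*p)


def gen_conformer_library(
    cluster_centers: Sequence[np.ndarray],
    members_per_cluster: int,
    angular_noise_sd: float,
    sequence: str,
    seed: int,
    geometry: BuilderGeometry = BuilderGeometry(),
) -> tuple[list[gemmi.Structure], SyntheticTruth]:
    """Peptide conformer library drawn from dihedral clusters plus noise.

    Each member's torsions are its cluster center plus wrapped-Gaussian
    noise of the given standard deviation; every member receives a random
    global rotation/translation (backbone torsions are invariant to rigid
    motion) and a random nominal resolution in [1.2, 3.0] Å so that
    reference selection has something to rank.  The truth records per
    member its cluster label and exact noisy torsions.
    """
    if angular_noise_sd < 0:
        raise ValueError("angular noise sd must be >= 0")
    rng = np.random.default_rng(seed)
    structures: list[gemmi.Structure] = []
    members: list[dict] = []
    for c, center in enumerate(cluster_centers):
        center = np.atleast_2d(np.asarray(center, float))
        if center.shape[0] != len(sequence):
            raise ValueError("cluster center length must match sequence length")
        for m in range(members_per_cluster):
            noise = rng.normal(0.0, angular_noise_sd, size=center.shape) if angular_noise_sd > 0 else 0.0
            dih = wrap_angle(center + noise)
            resolution = round(float(rng.uniform(1.2, 3.0)), 2)
            st = build_peptide(
                dih, sequence, geometry,
                name=f"SYNC{c}M{m:03d}", resolution=resolution,
            )
            _transform_structure(st, _random_rotation(rng), rng.uniform(-20, 20, 3))
            structures.append(st)
            members.append(
                {
                    "id": st.name,
                    "cluster": c,
                    "dihedrals": np.asarray(dih).tolist(),
                    "resolution": resolution,
                }
            )
    truth = SyntheticTruth(
        generator="gen_conformer_library",
        seed=seed,
        parameters={
            "n_clusters": len(cluster_centers),
            "members_per_cluster": members_per_cluster,
            "angular_noise_sd": angular_noise_sd,
            "sequence": sequence,
        },
        records={"members": members},
    )
    return structures, truth


# ---------------------------------------------------------------------------
# anchor scenes and mock receptors


def gen_anchor_scene(
    span: float = 27.5,
    contact_distance: float = 3.0,
    seed: int = 0,
):
    """Mock anchor scene with an exact Glu-OE-to-Arg-NH span.

    Layout (before a random global rotation/translation): the Asp
    carboxylate OD pair sits 2.2 Å apart; the Arg NH pair is the OD pair
    displaced by ``contact_distance`` (so the minimum NH-OD distance equals
    it exactly); the nearest Glu OE atom lies ``span`` beyond the first NH
    along the same axis, with the metal pair just past the OE atoms, as in
    an active site where the phosphomimetic coordinates the metals.  The
    default span is the published two-fragment geometry (27.5 Å).
    """
    from .assembly import AnchorScene  # local import to avoid a cycle

    if span <= 0:
        raise ValueError("span must be positive")
    if contact_distance <= 0:
        raise ValueError("contact distance must be positive")
    rng = np.random.default_rng(seed)
    od = np.array([[0.0, 0.0, 0.0], [2.2, 0.0, 0.0]])
    nh = od + np.array([0.0, contact_distance, 0.0])
    oe1 = nh[0] + np.array([0.0, span, 0.0])
    oe = np.vstack([oe1, oe1 + np.array([-2.2, 0.0, 0.0])])
    mn = np.vstack(
        [oe1 + np.array([0.0, 2.1, 0.6]), oe1 + np.array([2.4, 2.3, -0.4])]
    )
    R = _random_rotation(rng)
    t = rng.uniform(-30, 30, 3)
    scene = AnchorScene(
        mn_positions=mn @ R.T + t,
        asp_od=od @ R.T + t,
        glu_oe_ref=oe @ R.T + t,
        arg_nh_ref=nh @ R.T + t,
        context_atoms=np.empty((0, 3)),
        metadata={"generator": "gen_anchor_scene", "seed": seed},
    )
    truth = SyntheticTruth(
        generator="gen_anchor_scene",
        seed=seed,
        parameters={"span": span, "contact_distance": contact_distance},
        records={"span": span, "contact_distance": contact_distance},
    )
    return scene, truth


def _add_residue(chain, name, seqid, atoms):
    res = gemmi.Residue()
    res.name = name
    res.seqid = gemmi.SeqId(seqid, " ")
    for aname, elem, pos in atoms:
        atom = gemmi.Atom()
        atom.name = aname
        atom.element = gemmi.Element(elem)
        atom.pos = gemmi.Position(*np.asarray(pos, float))
        atom.occ = 1.0
        res.add_atom(atom)
    chain.add_residue(res)


def build_mock_phosphatase(
    seed: int = 0,
    with_glu_mimetic: bool = False,
    with_asp_anchor: bool = False,
    anchor_distance: float = 26.0,
    transform: tuple[np.ndarray, np.ndarray] | None = None,
    name: str = "mockpp",
) -> gemmi.Structure:
    """Minimal di-metal phosphatase mock for the alignment/assembly pipeline.

    Chain C holds two Mn ions 3.3 Å apart and six coordinating residues
    (each with a liganding side-chain atom within 2.6 Å of a metal and a CA
    ~3.5 Å further out).  ``with_glu_mimetic`` adds a Glu whose OE atoms sit
    next to the metals, emulating a phosphomimetic substrate tag;
    ``with_asp_anchor`` adds a chain B Asp 197 whose carboxylate lies
    ``anchor_distance`` Å from the first metal, emulating the
    regulatory-subunit anchor.  ``transform`` applies (R, t) to everything,
    for constructing pre-transformed alignment donors.
    """
    rng = np.random.default_rng(seed)
    st = gemmi.Structure()
    st.name = name
    st.resolution = 2.0
    model = gemmi.Model("1")
    chain_c = gemmi.Chain("C")
    mn = np.array([[0.0, 0.0, 0.0], [3.3, 0.0, 0.0]])
    # six metal-coordinating residues fanned around the di-metal center
    lig_names = ["ASP", "HIS", "ASP", "ASN", "HIS", "HIS"]
    lig_atoms = ["OD1", "ND1", "OD2", "OD1", "NE2", "ND1"]
    directions = np.array(
        [
            [0.0, 1.0, 0.3], [0.0, -1.0, 0.4], [-0.8, 0.2, -0.6],
            [0.3, 0.9, -0.8], [0.5, -0.7, -0.7], [0.9, 0.1, 1.0],
        ]
    )
    directions /= np.linalg.norm(directions, axis=1, keepdims=True)
    for i in range(6):
        metal = mn[i % 2]
        lig = metal + 2.1 * directions[i]
        ca = metal + 5.6 * directions[i] + rng.normal(0, 0.05, 3)
        n = ca + np.array([1.2, 0.6, 0.0])
        c = ca + np.array([-0.9, 1.1, 0.3])
        o = c + np.array([0.4, 1.1, 0.2])
        _add_residue(
            chain_c, lig_names[i], 50 + i * 7,
            [
                ("N", "N", n), ("CA", "C", ca), ("C", "C", c), ("O", "O", o),
                (lig_atoms[i], "O" if lig_atoms[i].startswith("O") else "N", lig),
            ],
        )
    for i, pos in enumerate(mn):
        _add_residue(chain_c, "MN", 501 + i, [("MN", "Mn", pos)])
    if with_glu_mimetic:
        oe1 = np.array([1.0, 2.2, 0.9])
        oe2 = np.array([2.6, 2.4, 1.1])
        cd = (oe1 + oe2) / 2 + np.array([0.0, 1.0, 0.3])
        cg = cd + np.array([0.3, 1.4, 0.2])
        cb = cg + np.array([-0.4, 1.3, 0.5])
        ca = cb + np.array([0.5, 1.3, 0.1])
        _add_residue(
            chain_c, "GLU", 600,
            [
                ("N", "N", ca + np.array([1.3, 0.5, 0.0])),
                ("CA", "C", ca), ("C", "C", ca + np.array([-1.0, 1.0, 0.4])),
                ("O", "O", ca + np.array([-1.1, 2.2, 0.4])),
                ("CB", "C", cb), ("CG", "C", cg), ("CD", "C", cd),
                ("OE1", "O", oe1), ("OE2", "O", oe2),
            ],
        )
    model.add_chain(chain_c)
    if with_asp_anchor:
        chain_b = gemmi.Chain("B")
        od_mid = np.array([0.0, -anchor_distance, 0.0])
        od1 = od_mid + np.array([-1.1, 0.0, 0.0])
        od2 = od_mid + np.array([1.1, 0.0, 0.0])
        cg = od_mid + np.array([0.0, -1.2, 0.0])
        cb = cg + np.array([0.0, -1.3, 0.6])
        ca = cb + np.array([1.0, -1.0, 0.2])
        _add_residue(
            chain_b, "ASP", 197,
            [
                ("N", "N", ca + np.array([1.3, 0.4, 0.0])),
                ("CA", "C", ca), ("C", "C", ca + np.array([-0.9, -1.1, 0.3])),
                ("O", "O", ca + np.array([-0.8, -2.3, 0.3])),
                ("CB", "C", cb), ("CG", "C", cg),
                ("OD1", "O", od1), ("OD2", "O", od2),
            ],
        )
        # a shell of context atoms behind the anchor, for clash screening
        for k in range(8):
            ang = 2 * np.pi * k / 8
            pos = od_mid + np.array([6.0 * np.cos(ang), -4.0, 6.0 * np.sin(ang)])
            _add_residue(chain_b, "GLY", 300 + k, [("CA", "C", pos)])
        model.add_chain(chain_b)
    st.add_model(model)
    st.setup_entities()
    if transform is not None:
        R, t = transform
        _transform_structure(st, np.asarray(R, float), np.asarray(t, float))
    return st
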