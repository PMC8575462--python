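"""Two-fragment anchor model assembly and candidate peptide fitting.

The placement target ("anchor scene") combines, in one coordinate frame:
the di-metal (Mn2+) center of the phosphatase active site, the carboxylate
of the regulatory-subunit Asp anchor (B55α D197), reference Glu OE1/OE2
positions for the phosphomimetic in the active site (taken from an aligned
donor structure), and reference Arg NH1/NH2 positions placed in bidentate
geometry against the Asp carboxylate.  Candidate peptide fragments carrying
their own Glu/Arg anchor atoms are then superposed onto the references by
pair-fit least squares, scored by the summed displacement of their anchor
atoms, threaded with the target (p107) sequence, and ranked.

All placement steps that the original procedure performed interactively
are deterministic here: the Arg anchor is positioned by an exhaustive
orientation grid search (no randomness), and tie-breaks fall back to
lexicographic fragment ids.
"""

from __future__ import annotations

import itertools
import json
import warnings
from dataclasses import dataclass, field

import gemmi
import numpy as np

from .fragments import Fragment
from .geometry import RigidTransform, place_atom, superpose

__all__ = [
    "AnchorScene",
    "CandidateModel",
    "ModelConfig",
    "align_active_site",
    "find_metal_center",
    "place_arg_anchor",
    "assemble_anchor_scene",
    "fit_candidate",
    "thread_sequence",
    "rank_candidates",
    "select_best",
    "fragment_to_structure",
]

METAL_ELEMENTS = {"Mn", "Fe", "Zn", "Mg", "Ni"}
METAL_PAIR_CUTOFF = 5.0    # Å between the two ions of a di-metal center
COORDINATION_CUTOFF = 2.6  # Å metal-to-ligand-atom
CLASH_CUTOFF = 2.5         # Å heavy-atom contact treated as a clash


@dataclass(frozen=True)
class ModelConfig:
    contact_distance: float = 3.0   # Å, target min NH-OD distance
    span_filter: float = 20.0       # Å, minimum Glu-Arg span of usable fragments
    top_k: int = 20
    orientation_grid: float = 10.0  # degrees, anchor placement search step

    def __post_init__(self):
        for name in ("contact_distance", "span_filter", "top_k", "orientation_grid"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")


@dataclass
class AnchorScene:
    """The two-fragment placement target in receptor coordinates."""

    mn_positions: np.ndarray   # (2, 3)
    asp_od: np.ndarray         # (2, 3) OD1/OD2 of the anchor Asp
    glu_oe_ref: np.ndarray     # (k, 3) reference phosphomimetic OE atoms
    arg_nh_ref: np.ndarray     # (2, 3) reference Arg NH atoms
    context_atoms: np.ndarray = field(default_factory=lambda: np.empty((0, 3)))
    metadata: dict = field(default_factory=dict)

    def __post_init__(self):
        self.mn_positions = np.asarray(self.mn_positions, float).reshape(2, 3)
        self.asp_od = np.asarray(self.asp_od, float).reshape(-1, 3)
        self.glu_oe_ref = np.asarray(self.glu_oe_ref, float).reshape(-1, 3)
        self.arg_nh_ref = np.asarray(self.arg_nh_ref, float).reshape(-1, 3)
        self.context_atoms = np.asarray(self.context_atoms, float).reshape(-1, 3)
        if self.anchor_span <= 0:
            raise ValueError("anchor span must be positive")

    @property
    def anchor_span(self) -> float:
        """Minimum Glu-OE to Arg-NH distance: the distance a peptide must bridge."""
        d = np.linalg.norm(
            self.glu_oe_ref[:, None, :] - self.arg_nh_ref[None, :, :], axis=-1
        )
        return float(d.min())

    def span_table(self) -> dict[str, float]:
        """All OE x NH pair distances, keyed 'OEi-NHj'."""
        out = {}
        for i, oe in enumerate(self.glu_oe_ref):
            for j, nh in enumerate(self.arg_nh_ref):
                out[f"OE{i + 1}-NH{j + 1}"] = float(np.linalg.norm(oe - nh))
        return out

    def to_json(self, **kwargs) -> str:
        payload = {
            "mn_positions": self.mn_positions.tolist(),
            "asp_od": self.asp_od.tolist(),
            "glu_oe_ref": self.glu_oe_ref.tolist(),
            "arg_nh_ref": self.arg_nh_ref.tolist(),
            "context_atoms": self.context_atoms.tolist(),
            "anchor_span_A": self.anchor_span,
            "span_table_A": self.span_table(),
            "metadata": self.metadata,
        }
        return json.dumps(payload, **kwargs)

    @classmethod
    def from_json(cls, text: str) -> "AnchorScene":
        d = json.loads(text)
        return cls(
            mn_positions=np.array(d["mn_positions"]),
            asp_od=np.array(d["asp_od"]),
            glu_oe_ref=np.array(d["glu_oe_ref"]),
            arg_nh_ref=np.array(d["arg_nh_ref"]),
            context_atoms=np.array(d["context_atoms"]).reshape(-1, 3),
            metadata=d.get("metadata", {}),
        )


@dataclass
class CandidateModel:
    """A fitted (and optionally threaded) candidate peptide."""

    fragment: Fragment
    transform: RigidTransform
    displacement_score: float
    d_glu_mn: tuple[float, float]
    d_arg_d197: float
    rank: int | None = None

    @property
    def fragment_id(self) -> str:
        return self.fragment.id

    @property
    def combined_anchor_distance(self) -> float:
        """min OE-Mn plus min NH-OD: the final-selection criterion."""
        return min(self.d_glu_mn) + self.d_arg_d197


# ---------------------------------------------------------------------------
# metal centers and active-site alignment


def _atom_coords(st: gemmi.Structure):
    for chain in st[0]:
        for res in chain:
            for atom in res:
                yield chain.name, res, atom


def find_metal_center(st: gemmi.Structure):
    """Locate the di-metal center: two metal ions within 5 Å of each other.

    Returns (metal_positions (2,3), coordinating_residues) where the
    coordinating residues are amino acids with any atom within 2.6 Å of a
    metal, in author order.
    """
    metals = []
    for chain_name, res, atom in _atom_coords(st):
        if atom.element.name in METAL_ELEMENTS:
            metals.append((chain_name, res.seqid.num, np.array([atom.pos.x, atom.pos.y, atom.pos.z])))
    pair = None
    for a, b in itertools.combinations(range(len(metals)), 2):
        if np.linalg.norm(metals[a][2] - metals[b][2]) <= METAL_PAIR_CUTOFF:
            pair = (metals[a], metals[b])
            break
    if pair is None:
        raise ValueError(f"{st.name}: no di-metal center found")
    mpos = np.vstack([pair[0][2], pair[1][2]])
    coordinating = []
    for chain in st[0]:
        for res in chain:
            info = gemmi.find_tabulated_residue(res.name)
            if info is None or not info.is_amino_acid():
                continue
            close = False
            for atom in res:
                p = np.array([atom.pos.x, atom.pos.y, atom.pos.z])
                if np.min(np.linalg.norm(mpos - p, axis=1)) <= COORDINATION_CUTOFF:
                    close = True
                    break
            if close:
                coordinating.append((chain.name, res))
    return mpos, coordinating


def _lcs_pairing(names_a, names_b):
    """Longest common subsequence index pairs between two name lists."""
    na, nb = len(names_a), len(names_b)
    L = np.zeros((na + 1, nb + 1), dtype=int)
    for i in range(na - 1, -1, -1):
        for j in range(nb - 1, -1, -1):
            if names_a[i] == names_b[j]:
                L[i, j] = 1 + L[i + 1, j + 1]
            else:
                L[i, j] = max(L[i + 1, j], L[i, j + 1])
    pairs = []
    i = j = 0
    while i < na and j < nb:
        if names_a[i] == names_b[j]:
            pairs.append((i, j))
            i += 1
            j += 1
        elif L[i + 1, j] >= L[i, j + 1]:
            i += 1
        else:
            j += 1
    return pairs


def align_active_site(holoenzyme: gemmi.Structure, donor: gemmi.Structure) -> RigidTransform:
    """Superpose the donor catalytic site onto the holoenzyme's.

    The paired point set is the two metals plus CA atoms of the
    metal-coordinating residues (identified by a < 2.6 Å metal-ligand
    contact).  Coordinating residues are paired in author order, falling
    back to a longest-common-subsequence match on residue names when the
    two sites disagree in count; both metal orderings are tried and the
    lower-RMSD one kept.
    """
    holo_m, holo_res = find_metal_center(holoenzyme)
    don_m, don_res = find_metal_center(donor)

    def cas(res_list):
        names, coords = [], []
        for _, res in res_list:
            atom = res.find_atom("CA", "*")
            if atom is not None:
                names.append(res.name)
                coords.append([atom.pos.x, atom.pos.y, atom.pos.z])
        return names, np.array(coords)

    holo_names, holo_ca = cas(holo_res)
    don_names, don_ca = cas(don_res)
    if len(holo_names) == len(don_names):
        pairs = list(zip(range(len(don_names)), range(len(holo_names))))
    else:
        pairs = _lcs_pairing(don_names, holo_names)
    if len(pairs) < 1:
        raise ValueError("no common coordinating residues to align on")
    mob_ca = don_ca[[i for i, _ in pairs]]
    tgt_ca = holo_ca[[j for _, j in pairs]]
    best = None
    for order in ((0, 1), (1, 0)):
        mobile = np.vstack([don_m[list(order)], mob_ca])
        target = np.vstack([holo_m, tgt_ca])
        tform, rmsd = superpose(mobile, target)
        if best is None or rmsd < best[1]:
            best = (tform, rmsd)
    tform, rmsd = best
    if rmsd > 3.0:
        warnings.warn(
            f"active-site alignment RMSD {rmsd:.2f} Å is large; "
            "donor may not share the catalytic fold",
            stacklevel=2,
        )
    return tform


# ---------------------------------------------------------------------------
# Arg anchor placement


def _direction_grid(step_deg: float) -> np.ndarray:
    thetas = np.radians(np.arange(0.0, 180.0 + 1e-9, step_deg))
    phis = np.radians(np.arange(0.0, 360.0, step_deg))
    dirs = [np.array([0.0, 0.0, 1.0]), np.array([0.0, 0.0, -1.0])]
    for th in thetas:
        s = np.sin(th)
        if s < 1e-9:
            continue
        for ph in phis:
            dirs.append(np.array([s * np.cos(ph), s * np.sin(ph), np.cos(th)]))
    return np.array(dirs)


def _nh_for_direction(asp_od: np.ndarray, d: np.ndarray, contact: float) -> np.ndarray | None:
    """NH pair = OD pair displaced by t*d with min NH-OD distance == contact."""
    v = asp_od[1] - asp_od[0]
    dv = float(d @ v)
    t = contact
    if dv > 0:
        # the cross pair NH1-OD2 (or NH2-OD1) may dip below t; enlarge t so
        # the minimum over all four pairs lands exactly on the contact value
        disc = dv * dv - float(v @ v) + contact * contact
        if disc >= 0:
            t = max(t, dv + np.sqrt(disc))
    nh = asp_od + t * d
    dmat = np.linalg.norm(nh[:, None, :] - asp_od[None, :, :], axis=-1)
    if abs(dmat.min() - contact) > 1e-6:
        return None
    return nh


def place_arg_anchor(
    context_atoms: np.ndarray,
    asp_od: np.ndarray,
    config: ModelConfig = ModelConfig(),
) -> tuple[np.ndarray, bool]:
    """Place Arg NH1/NH2 in bidentate geometry against an Asp carboxylate.

    The NH pair is the OD pair displaced along a trial direction, scaled so
    the minimum NH-OD distance equals ``config.contact_distance`` exactly.
    Directions are enumerated on a deterministic spherical grid
    (``config.orientation_grid`` degrees); the orientation with the fewest
    heavy-atom clashes (< 2.5 Å to a context atom) wins, ties broken toward
    the largest clearance and then grid order.  Returns (nh_positions,
    clash_free).  If no orientation is clash-free the least-clashing one is
    returned with a warning and ``clash_free=False``.
    """
    asp_od = np.asarray(asp_od, float).reshape(2, 3)
    context = np.asarray(context_atoms, float).reshape(-1, 3)
    best = None
    for idx, d in enumerate(_direction_grid(config.orientation_grid)):
        nh = _nh_for_direction(asp_od, d, config.contact_distance)
        if nh is None:
            continue
        if len(context):
            dists = np.linalg.norm(nh[:, None, :] - context[None, :, :], axis=-1)
            clashes = int((dists < CLASH_CUTOFF).sum())
            clearance = float(dists.min())
        else:
            clashes, clearance = 0, np.inf
        key = (clashes, -clearance, idx)
        if best is None or key < best[0]:
            best = (key, nh)
    if best is None:
        raise ValueError("no feasible anchor orientation on the search grid")
    (clashes, _, _), nh = best
    if clashes > 0:
        warnings.warn(
            f"no clash-free Arg anchor orientation; best has {clashes} contacts "
            f"< {CLASH_CUTOFF} Å",
            stacklevel=2,
        )
    return nh, clashes == 0


# ---------------------------------------------------------------------------
# scene assembly


def _find_anchor_asp(holo: gemmi.Structure, mn_mid: np.ndarray,
                     residue_name="ASP", residue_number=197):
    candidates = []
    for chain in holo[0]:
        for res in chain:
            if res.name == residue_name and res.seqid.num == residue_number:
                od1 = res.find_atom("OD1", "*")
                od2 = res.find_atom("OD2", "*")
                if od1 is None or od2 is None:
                    continue
                od = np.array(
                    [[od1.pos.x, od1.pos.y, od1.pos.z], [od2.pos.x, od2.pos.y, od2.pos.z]]
                )
                candidates.append((chain.name, res, od))
    if not candidates:
        raise ValueError(
            f"holoenzyme lacks an anchor residue {residue_name}{residue_number} "
            "with a complete carboxylate"
        )
    return min(candidates, key=lambda c: np.linalg.norm(c[2].mean(axis=0) - mn_mid))


def _donor_phosphomimetic_oe(donor: gemmi.Structure, don_metals: np.ndarray) -> np.ndarray:
    best = None
    for chain in donor[0]:
        for res in chain:
            if res.name != "GLU":
                continue
            oe = []
            for name in ("OE1", "OE2"):
                atom = res.find_atom(name, "*")
                if atom is not None:
                    oe.append([atom.pos.x, atom.pos.y, atom.pos.z])
            if not oe:
                continue
            oe = np.array(oe)
            d = float(
                np.linalg.norm(
                    oe[:, None, :] - don_metals[None, :, :], axis=-1
                ).min()
            )
            if best is None or d < best[0]:
                best = (d, oe)
    if best is None or best[0] > 8.0:
        raise ValueError("donor has no Glu phosphomimetic near its metal center")
    return best[1]


def assemble_anchor_scene(
    holoenzyme: gemmi.Structure,
    donor: gemmi.Structure,
    reference_fragment: Fragment | None = None,
    config: ModelConfig = ModelConfig(),
    anchor_residue: tuple[str, int] = ("ASP", 197),
    context_radius: float = 12.0,
) -> AnchorScene:
    """Build the two-fragment placement target from receptor + donor.

    Metals and the anchor Asp carboxylate come from the holoenzyme; the
    phosphomimetic Glu OE reference comes from the donor after active-site
    alignment; the Arg NH reference is placed against the Asp carboxylate
    by grid search.  ``reference_fragment`` (e.g. the best-resolution
    conformer of the mined Arg-motif cluster) is recorded in the metadata
    and its Arg NH pair geometry sanity-checked against the placement.
    """
    tform = align_active_site(holoenzyme, donor)
    holo_m, _ = find_metal_center(holoenzyme)
    don_m, _ = find_metal_center(donor)
    glu_oe = tform.apply(_donor_phosphomimetic_oe(donor, don_m))
    chain_name, asp_res, asp_od = _find_anchor_asp(
        holoenzyme, holo_m.mean(axis=0), *anchor_residue
    )
    od_mid = asp_od.mean(axis=0)
    context = []
    for cname, res, atom in _atom_coords(holoenzyme):
        if atom.element.name == "H":
            continue
        if res.name == asp_res.name and res.seqid.num == asp_res.seqid.num and cname == chain_name:
            continue
        p = np.array([atom.pos.x, atom.pos.y, atom.pos.z])
        if np.linalg.norm(p - od_mid) <= context_radius:
            context.append(p)
    context = np.array(context) if context else np.empty((0, 3))
    arg_nh, clash_free = place_arg_anchor(context, asp_od, config)
    metadata = {
        "holoenzyme": holoenzyme.name,
        "donor": donor.name,
        "anchor_chain": chain_name,
        "anchor_residue": f"{anchor_residue[0]}{anchor_residue[1]}",
        "clash_free": clash_free,
        "contact_distance_A": config.contact_distance,
    }
    if reference_fragment is not None:
        metadata["reference_fragment"] = reference_fragment.id
        nh = reference_fragment.marked_atoms.get("ARG_NH")
        if nh is not None and len(nh) == 2:
            metadata["reference_nh_nh_A"] = float(np.linalg.norm(nh[0] - nh[1]))
    return AnchorScene(
        mn_positions=holo_m,
        asp_od=asp_od,
        glu_oe_ref=glu_oe,
        arg_nh_ref=arg_nh,
        context_atoms=context,
        metadata=metadata,
    )


# ---------------------------------------------------------------------------
# candidate fitting, threading, ranking


def _anchor_pairings(n_atoms: int, n_ref: int):
    """Injective assignments of fragment anchor atoms to reference atoms."""
    return list(itertools.permutations(range(n_ref), n_atoms))


def _two_point_fit(mobile: np.ndarray, target: np.ndarray) -> RigidTransform:
    """Optimal rigid fit of a 2-point segment onto a 2-point reference.

    Rotating the mobile segment parallel to the target segment and
    centering the leftover length symmetrically minimizes the summed
    endpoint displacement, which equals |d - s| for segment lengths d, s.
    """
    v_m = mobile[1] - mobile[0]
    v_t = target[1] - target[0]
    s = np.linalg.norm(v_m)
    d = np.linalg.norm(v_t)
    if s < 1e-12 or d < 1e-12:
        return RigidTransform(np.eye(3), target.mean(axis=0) - mobile.mean(axis=0))
    a = v_m / s
    b = v_t / d
    c = float(np.clip(a @ b, -1.0, 1.0))
    axis = np.cross(a, b)
    n = np.linalg.norm(axis)
    if n < 1e-12:
        if c > 0:
            R = np.eye(3)
        else:  # antiparallel: rotate 180 deg about any axis orthogonal to a
            perp = np.eye(3)[np.argmin(np.abs(a))]
            axis = np.cross(a, perp)
            axis /= np.linalg.norm(axis)
            R = _rotation_about(axis, np.pi)
    else:
        axis = axis / n
        R = _rotation_about(axis, np.arctan2(n, c))
    t = target.mean(axis=0) - R @ mobile.mean(axis=0)
    return RigidTransform(R, t)


def _rotation_about(axis: np.ndarray, angle: float) -> np.ndarray:
    """Rodrigues rotation matrix about a unit axis."""
    K = np.array(
        [[0, -axis[2], axis[1]], [axis[2], 0, -axis[0]], [-axis[1], axis[0], 0]]
    )
    return np.eye(3) + np.sin(angle) * K + (1 - np.cos(angle)) * (K @ K)


def fit_candidate(fragment: Fragment, scene: AnchorScene) -> CandidateModel:
    """Pair-fit a fragment's Glu/Arg anchor atoms onto the scene references.

    OE1/OE2 and NH1/NH2 labelling in deposited structures is arbitrary, so
    both assignments are tried per side and the lowest displacement score
    kept.  The score is the sum of distances of each fitted anchor atom to
    its reference counterpart (the pair-fit residual is its least-squares
    sibling); Mn and D197 distances are measured in the fitted pose.
    """
    try:
        oe = fragment.marked_atoms["GLU_OE"]
        nh = fragment.marked_atoms["ARG_NH"]
    except KeyError as exc:
        raise ValueError(f"{fragment.id}: missing marked anchor atoms") from exc
    best = None
    for oe_asn in _anchor_pairings(len(oe), len(scene.glu_oe_ref)):
        for nh_asn in _anchor_pairings(len(nh), len(scene.arg_nh_ref)):
            mobile = np.vstack([oe, nh])
            target = np.vstack(
                [scene.glu_oe_ref[list(oe_asn)], scene.arg_nh_ref[list(nh_asn)]]
            )
            if len(mobile) == 2:
                tform = _two_point_fit(mobile, target)
            elif len(mobile) < 2:
                raise ValueError(
                    f"{fragment.id}: fewer than 2 anchor atoms; pair-fit underdetermined"
                )
            else:
                tform, _ = superpose(mobile, target)
            score = float(
                np.linalg.norm(tform.apply(mobile) - target, axis=1).sum()
            )
            if best is None or score < best[0]:
                best = (score, tform)
    score, tform = best
    fitted_oe = tform.apply(oe)
    fitted_nh = tform.apply(nh)
    d_glu_mn = tuple(
        float(np.linalg.norm(fitted_oe - m, axis=1).min()) for m in scene.mn_positions
    )
    d_arg = float(
        np.linalg.norm(
            fitted_nh[:, None, :] - scene.asp_od[None, :, :], axis=-1
        ).min()
    )
    return CandidateModel(
        fragment=fragment,
        transform=tform,
        displacement_score=score,
        d_glu_mn=d_glu_mn,
        d_arg_d197=d_arg,
    )


_EXTENSION_TORSIONS = (-139.0, 135.0, 180.0)  # extended (beta) builder defaults


def thread_sequence(
    fragment: Fragment,
    target_core: str,
    prefix: str = "",
    suffix: str = "",
    numbering_offset: int = 1,
) -> Fragment:
    """Thread a target sequence onto a fragment's core backbone.

    Core residues keep their backbone (and CB) coordinates bit-for-bit and
    are renamed to ``target_core``; wildcard flanks are dropped; ``prefix``
    and ``suffix`` residues are built in extended conformation by
    internal-coordinate placement off the core termini.  Side chains beyond
    CB are dropped, except the anchor Glu OE / Arg NH atoms, which are
    preserved untouched.  Author numbering starts at ``numbering_offset``.
    """
    from .synthetic import BuilderGeometry  # stereochemistry constants

    core = slice(fragment.core_start, fragment.core_end)
    core_len = fragment.core_end - fragment.core_start
    if len(target_core) != core_len:
        raise ValueError(
            f"target core length {len(target_core)} != fragment core length {core_len}"
        )
    g = BuilderGeometry()
    phi_e, psi_e, omega_e = _EXTENSION_TORSIONS
    core_bb = fragment.backbone[core].copy()
    core_cb = fragment.cb[core].copy()

    def _carbonyl_o(N, CA, C, psi):
        return place_atom(N, CA, C, g.bond_c_o, g.angle_ca_c_o, psi + 180.0)

    def _cbeta(N, CA, C):
        return place_atom(C, N, CA, g.bond_ca_cb, g.angle_n_ca_cb, g.torsion_c_n_ca_cb)

    prefix_bb = []
    N1, CA1, C1 = core_bb[0, 0], core_bb[0, 1], core_bb[0, 2]
    for _ in prefix:
        Cp = place_atom(C1, CA1, N1, g.bond_c_n, g.angle_c_n_ca, phi_e)
        CAp = place_atom(CA1, N1, Cp, g.bond_ca_c, g.angle_ca_c_n, omega_e)
        Np = place_atom(N1, Cp, CAp, g.bond_n_ca, g.angle_n_ca_c, psi_e)
        Op = _carbonyl_o(Np, CAp, Cp, psi_e)
        prefix_bb.insert(0, np.array([Np, CAp, Cp, Op]))
        N1, CA1, C1 = Np, CAp, Cp
    suffix_bb = []
    Nl, CAl, Cl = core_bb[-1, 0], core_bb[-1, 1], core_bb[-1, 2]
    for _ in suffix:
        Nn = place_atom(Nl, CAl, Cl, g.bond_c_n, g.angle_ca_c_n, psi_e)
        CAn = place_atom(CAl, Cl, Nn, g.bond_n_ca, g.angle_c_n_ca, omega_e)
        Cn = place_atom(Cl, Nn, CAn, g.bond_ca_c, g.angle_n_ca_c, phi_e)
        On = _carbonyl_o(Nn, CAn, Cn, psi_e)
        suffix_bb.append(np.array([Nn, CAn, Cn, On]))
        Nl, CAl, Cl = Nn, CAn, Cn

    seq = prefix + target_core + suffix
    n = len(seq)
    backbone = np.vstack(
        [np.array(prefix_bb).reshape(-1, 4, 3) if prefix_bb else np.empty((0, 4, 3)),
         core_bb,
         np.array(suffix_bb).reshape(-1, 4, 3) if suffix_bb else np.empty((0, 4, 3))]
    )
    cb = np.full((n, 3), np.nan)
    cb[len(prefix) : len(prefix) + core_len] = core_cb
    for i, letter in enumerate(seq):
        if np.isnan(cb[i]).any() and letter != "G":
            cb[i] = _cbeta(backbone[i, 0], backbone[i, 1], backbone[i, 2])
    numbers = list(range(numbering_offset, numbering_offset + n))
    return Fragment(
        structure_id=fragment.structure_id,
        chain_id=fragment.chain_id,
        start_seqid=str(numbers[0]),
        end_seqid=str(numbers[-1]),
        sequence=seq,
        core_start=0,
        core_end=n,
        backbone=backbone,
        cb=cb,
        residue_numbers=numbers,
        marked_atoms={k: v.copy() for k, v in fragment.marked_atoms.items()},
        resolution=fragment.resolution,
    )


def rank_candidates(
    candidates: list[CandidateModel], config: ModelConfig = ModelConfig()
) -> list[CandidateModel]:
    """Sort ascending by displacement score (ties by fragment id); keep top_k."""
    if not candidates:
        raise ValueError("no candidates to rank")
    ordered = sorted(candidates, key=lambda c: (c.displacement_score, c.fragment_id))
    retained = ordered[: config.top_k]
    for i, cand in enumerate(retained):
        cand.rank = i + 1
    return retained


def select_best(ranked: list[CandidateModel]) -> CandidateModel:
    """Among retained candidates, the one nearest the Mn pair and the Asp anchor."""
    if not ranked:
        raise ValueError("empty candidate list")
    return min(ranked, key=lambda c: (c.combined_anchor_distance, c.fragment_id))


# ---------------------------------------------------------------------------
# model output


_THREE_LETTER = {
    "A": "ALA", "R": "ARG", "N": "ASN", "D": "ASP", "C": "CYS",
    "Q": "GLN", "E": "GLU", "G": "GLY", "H": "HIS", "I": "ILE",
    "L": "LEU", "K": "LYS", "M": "MET", "F": "PHE", "P": "PRO",
    "S": "SER", "T": "THR", "W": "TRP", "Y": "TYR", "V": "VAL",
}


def fragment_to_structure(fragment: Fragment, name: str | None = None) -> gemmi.Structure:
    """Export a fragment as a coordinate structure (occupancy 1, no hydrogens)."""
    st = gemmi.Structure()
    st.name = name or fragment.id
    model = gemmi.Model("1")
    chain = gemmi.Chain(fragment.chain_id or "A")
    numbers = fragment.residue_numbers or list(range(1, len(fragment) + 1))
    marked_by_residue = _marked_atoms_by_residue(fragment)
    for i, letter in enumerate(fragment.sequence):
        res = gemmi.Residue()
        res.name = _THREE_LETTER.get(letter.upper(), "UNK")
        res.seqid = gemmi.SeqId(int(numbers[i]), " ")
        entries = [
            ("N", "N", fragment.backbone[i, 0]),
            ("CA", "C", fragment.backbone[i, 1]),
            ("C", "C", fragment.backbone[i, 2]),
            ("O", "O", fragment.backbone[i, 3]),
        ]
        if not np.isnan(fragment.cb[i]).any():
            entries.append(("CB", "C", fragment.cb[i]))
        entries.extend(marked_by_residue.get(i, []))
        for aname, elem, pos in entries:
            atom = gemmi.Atom()
            atom.name = aname
            atom.element = gemmi.Element(elem)
            atom.pos = gemmi.Position(*np.asarray(pos, float))
            atom.occ = 1.0
            res.add_atom(atom)
        chain.add_residue(res)
    model.add_chain(chain)
    st.add_model(model)
    st.setup_entities()
    return st


def _marked_atoms_by_residue(fragment: Fragment) -> dict[int, list]:
    """Attach marked anchor atoms to the nearest same-type residue by CB."""
    out: dict[int, list] = {}
    for role, names, letter, elem in (
        ("GLU_OE", ("OE1", "OE2"), "E", "O"),
        ("ARG_NH", ("NH1", "NH2"), "R", "N"),
    ):
        coords = fragment.marked_atoms.get(role)
        if coords is None:
            continue
        idx_candidates = [i for i, ch in enumerate(fragment.sequence) if ch == letter]
        if not idx_candidates:
            continue
        centroid = coords.mean(axis=0)
        idx = min(
            idx_candidates,
            key=lambda i: np.linalg.norm(fragment.backbone[i, 1] - centroid),
        )
        out.setdefault(idx, []).extend(
            (names[k], elem, coords[k]) for k in range(len(coords))
        )
    return out
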