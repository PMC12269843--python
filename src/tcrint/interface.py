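"""Interface analysis: buried surface area, contacts, docking geometry.

The TCR-pMHC interface is characterized the way structural immunology
papers report it:

* buried surface area (BSA) = SASA(TCR) + SASA(pMHC) - SASA(complex),
  decomposed per residue, per CDR/framework region and per TCR chain;
* atom-pair contacts classified purely by distance cutoffs
  (hydrogen bond 3.5 A, van der Waals 4.0 A, salt bridge 4.0 A,
  disulfide 4.5 A), heavy atoms only;
* docking angle between the Valpha->Vbeta centroid vector and the
  least-squares axis of the bound peptide, folded to [0, 90] degrees;
* Kabsch least-squares superposition for apo/holo r.m.s.d.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.spatial import cKDTree

from .sasa import SasaParams, atoms_of, compute_sasa
from .structure import AnnotatedComplex, Atom, RegionAnnotation, RegisterMap, Residue

__all__ = [
    "InterfaceError",
    "BsaBreakdown",
    "ContactCriteria",
    "Contact",
    "ContactSet",
    "DockingGeometry",
    "Superposition",
    "compute_bsa",
    "detect_contacts",
    "summarize_footprint",
    "docking_geometry",
    "superpose",
    "match_calpha",
    "TCR_SIDE",
    "PMHC_SIDE",
]

TCR_SIDE = ("tcr_alpha", "tcr_beta")
PMHC_SIDE = ("mhc_alpha", "mhc_beta", "peptide")

#: report order of TCR-side region labels (alpha then beta chain)
REGION_LABELS = [
    "CDR1a", "CDR2a", "CDR3a", "FWa",
    "CDR1b", "CDR2b", "CDR3b", "FWb",
]

_CHAIN_SUFFIX = {"tcr_alpha": "a", "tcr_beta": "b"}

KIND_PRECEDENCE = ("disulfide", "salt_bridge", "hbond", "vdw")

#: positively / negatively charged side-chain group atoms (heavy-atom,
#: residue-name keyed). Citrulline (CIR) is neutral and deliberately absent.
_POSITIVE_ATOMS = {("LYS", "NZ"), ("ARG", "NH1"), ("ARG", "NH2"), ("ARG", "NE")}
_NEGATIVE_ATOMS = {("ASP", "OD1"), ("ASP", "OD2"), ("GLU", "OE1"), ("GLU", "OE2")}

_POLAR_ELEMENTS = {"N", "O", "S"}


class InterfaceError(ValueError):
    """Interface computation requested on an invalid chain arrangement."""


# ---------------------------------------------------------------------------
# buried surface area

@dataclass
class BsaBreakdown:
    """Buried-surface-area accounting over a two-sided interface.

    ``total_bsa`` is the two-sided sum SASA(side A) + SASA(side B)
    - SASA(complex). Region percentages partition the TCR-side burial
    and therefore sum to 100.
    """

    total_bsa: float
    tcr_side_bsa: float
    pmhc_side_bsa: float
    per_residue: dict[tuple[str, int, str], float]
    per_region_pct: dict[str, float]
    chain_share_pct: dict[str, float]

    def to_dict(self) -> dict:
        return {
            "total_bsa_A2": round(self.total_bsa, 1),
            "tcr_side_bsa_A2": round(self.tcr_side_bsa, 1),
            "pmhc_side_bsa_A2": round(self.pmhc_side_bsa, 1),
            "chain_share_pct": {k: round(v, 1) for k, v in self.chain_share_pct.items()},
            "per_region_pct": {k: round(v, 1) for k, v in self.per_region_pct.items()},
        }


def _region_of(cx: AnnotatedComplex, role: str, res: Residue) -> str | None:
    ann = cx.regions.get(role)
    if ann is None:
        return None
    label = ann.label_of(*res.key)
    if label is None:
        return None
    return f"{label}{_CHAIN_SUFFIX[role]}"


def compute_bsa(
    cx: AnnotatedComplex,
    params: SasaParams | None = None,
    *,
    side_a: tuple[str, ...] = TCR_SIDE,
    side_b: tuple[str, ...] = PMHC_SIDE,
) -> BsaBreakdown:
    """Buried surface area of the interface between two groups of chains.

    Per-residue burial is the drop in that residue's SASA from the
    isolated side to the complex; with a shared deterministic sample
    lattice this drop is non-negative atom by atom.
    """
    params = params or SasaParams()
    res_a = cx.residues(*side_a)
    res_b = cx.residues(*side_b)
    if not res_a or not res_b:
        raise InterfaceError(
            "both interface sides need at least one chain with residues"
        )

    atoms_a = atoms_of(res_a)
    atoms_b = atoms_of(res_b)
    sasa_a = compute_sasa(atoms_a, params)
    sasa_b = compute_sasa(atoms_b, params)
    sasa_ab = compute_sasa(atoms_a + atoms_b, params)

    delta_a = sasa_a - sasa_ab[: len(atoms_a)]
    delta_b = sasa_b - sasa_ab[len(atoms_a):]
    total = float(delta_a.sum() + delta_b.sum())

    per_residue: dict[tuple[str, int, str], float] = {}
    i = 0
    for res in res_a:
        k = len(res.heavy_atoms())
        per_residue[(res.chain_id, res.seq_id, res.icode)] = float(
            delta_a[i : i + k].sum()
        )
        i += k
    i = 0
    for res in res_b:
        k = len(res.heavy_atoms())
        per_residue[(res.chain_id, res.seq_id, res.icode)] = float(
            delta_b[i : i + k].sum()
        )
        i += k

    # TCR-side decomposition by chain and region
    chain_burial = {"alpha": 0.0, "beta": 0.0}
    region_burial = {label: 0.0 for label in REGION_LABELS}
    for role, chain_key in (("tcr_alpha", "alpha"), ("tcr_beta", "beta")):
        for res in cx.chains.get(role, []):
            burial = per_residue.get((res.chain_id, res.seq_id, res.icode), 0.0)
            chain_burial[chain_key] += burial
            region = _region_of(cx, role, res)
            if region is not None:
                region_burial[region] = region_burial.get(region, 0.0) + burial

    tcr_side = sum(
        per_residue.get((res.chain_id, res.seq_id, res.icode), 0.0)
        for role in TCR_SIDE
        for res in cx.chains.get(role, [])
    )
    pmhc_side = total - tcr_side

    # percentages partition the labelled (variable-domain) burial, so they
    # always sum to 100 even when a trace of constant-domain burial exists
    labelled = sum(region_burial.values())
    if labelled > 0:
        per_region_pct = {k: 100.0 * v / labelled for k, v in region_burial.items()}
    else:
        per_region_pct = {k: 0.0 for k in region_burial}
    if tcr_side > 0:
        chain_share_pct = {k: 100.0 * v / tcr_side for k, v in chain_burial.items()}
    else:
        chain_share_pct = {k: 0.0 for k in chain_burial}

    return BsaBreakdown(
        total_bsa=total,
        tcr_side_bsa=tcr_side,
        pmhc_side_bsa=pmhc_side,
        per_residue=per_residue,
        per_region_pct=per_region_pct,
        chain_share_pct=chain_share_pct,
    )


# ---------------------------------------------------------------------------
# contacts

@dataclass(frozen=True)
class ContactCriteria:
    """Distance cutoffs (Angstrom) for each contact class."""

    hbond: float = 3.5
    vdw: float = 4.0
    disulfide: float = 4.5
    salt_bridge: float = 4.0

    @property
    def max_cutoff(self) -> float:
        return max(self.hbond, self.vdw, self.disulfide, self.salt_bridge)


@dataclass(frozen=True)
class Contact:
    """One classified inter-side atom pair.

    ``kinds`` lists every class the pair satisfies, most specific first
    (disulfide > salt_bridge > hbond > vdw).
    """

    atom_a: tuple[str, str, int, str]  # chain, resname, seq_id, atom
    atom_b: tuple[str, str, int, str]
    role_a: str
    role_b: str
    distance: float
    kinds: tuple[str, ...]


@dataclass
class ContactSet:
    contacts: list[Contact] = field(default_factory=list)

    def __len__(self) -> int:
        return len(self.contacts)

    def __iter__(self):
        return iter(self.contacts)

    def of_kind(self, kind: str) -> list[Contact]:
        return [c for c in self.contacts if kind in c.kinds]

    def as_pair_set(self) -> set[tuple]:
        """Hashable view for equality checks between detection methods."""
        return {(c.atom_a, c.atom_b, c.kinds) for c in self.contacts}

    def to_dataframe(self) -> pd.DataFrame:
        rows = [
            {
                "chain_a": c.atom_a[0], "resname_a": c.atom_a[1],
                "seq_id_a": c.atom_a[2], "atom_a": c.atom_a[3],
                "chain_b": c.atom_b[0], "resname_b": c.atom_b[1],
                "seq_id_b": c.atom_b[2], "atom_b": c.atom_b[3],
                "role_a": c.role_a, "role_b": c.role_b,
                "distance_A": round(c.distance, 2),
                "kind": c.kinds[0],
                "kinds": "+".join(c.kinds),
            }
            for c in self.contacts
        ]
        cols = ["chain_a", "resname_a", "seq_id_a", "atom_a",
                "chain_b", "resname_b", "seq_id_b", "atom_b",
                "role_a", "role_b", "distance_A", "kind", "kinds"]
        return pd.DataFrame(rows, columns=cols)

    def to_tsv(self, path) -> None:
        self.to_dataframe().to_csv(path, sep="\t", index=False)


def _classify_pair(res_a: Residue, atom_a: Atom, res_b: Residue, atom_b: Atom,
                   d: float, crit: ContactCriteria) -> tuple[str, ...]:
    kinds: list[str] = []
    ea = atom_a.element.strip().upper()
    eb = atom_b.element.strip().upper()
    if (
        d <= crit.disulfide
        and atom_a.name == "SG"
        and atom_b.name == "SG"
        and ea == eb == "S"
    ):
        kinds.append("disulfide")
    key_a = (res_a.name.upper(), atom_a.name)
    key_b = (res_b.name.upper(), atom_b.name)
    if d <= crit.salt_bridge and (
        (key_a in _POSITIVE_ATOMS and key_b in _NEGATIVE_ATOMS)
        or (key_a in _NEGATIVE_ATOMS and key_b in _POSITIVE_ATOMS)
    ):
        kinds.append("salt_bridge")
    if (
        d <= crit.hbond
        and ea in _POLAR_ELEMENTS
        and eb in _POLAR_ELEMENTS
        and not (ea == "S" and eb == "S")
    ):
        kinds.append("hbond")
    if d <= crit.vdw:
        kinds.append("vdw")
    return tuple(kinds)


def _flatten_side(cx: AnnotatedComplex, roles: tuple[str, ...]):
    atoms, meta = [], []
    for role in roles:
        for res in cx.chains.get(role, []):
            for a in res.heavy_atoms():
                atoms.append(a)
                meta.append((res, role))
    return atoms, meta


def detect_contacts(
    cx: AnnotatedComplex,
    criteria: ContactCriteria | None = None,
    *,
    side_a: tuple[str, ...] = TCR_SIDE,
    side_b: tuple[str, ...] = PMHC_SIDE,
    method: str = "grid",
) -> ContactSet:
    """Find and classify all inter-side heavy-atom contacts.

    ``method="grid"`` uses a k-d tree restricted to the largest cutoff;
    ``method="brute"`` scans every pair. Both must return identical
    sets (the brute path is kept as a correctness oracle).
    An empty interface yields an empty ContactSet, not an error.
    """
    crit = criteria or ContactCriteria()
    atoms_a, meta_a = _flatten_side(cx, side_a)
    atoms_b, meta_b = _flatten_side(cx, side_b)
    if not atoms_a or not atoms_b:
        return ContactSet([])

    coords_a = np.array([a.coords for a in atoms_a])
    coords_b = np.array([a.coords for a in atoms_b])

    if method == "grid":
        tree_a = cKDTree(coords_a)
        tree_b = cKDTree(coords_b)
        pair_lists = tree_a.query_ball_tree(tree_b, crit.max_cutoff)
        candidates = [(i, j) for i, js in enumerate(pair_lists) for j in js]
    elif method == "brute":
        candidates = [
            (i, j) for i in range(len(atoms_a)) for j in range(len(atoms_b))
            if np.linalg.norm(coords_a[i] - coords_b[j]) <= crit.max_cutoff
        ]
    else:
        raise ValueError(f"unknown method {method!r}")

    contacts: list[Contact] = []
    for i, j in candidates:
        d = float(np.linalg.norm(coords_a[i] - coords_b[j]))
        res_a, role_a = meta_a[i]
        res_b, role_b = meta_b[j]
        kinds = _classify_pair(res_a, atoms_a[i], res_b, atoms_b[j], d, crit)
        if kinds:
            contacts.append(
                Contact(
                    atom_a=(res_a.chain_id, res_a.name, res_a.seq_id, atoms_a[i].name),
                    atom_b=(res_b.chain_id, res_b.name, res_b.seq_id, atoms_b[j].name),
                    role_a=role_a,
                    role_b=role_b,
                    distance=d,
                    kinds=kinds,
                )
            )
    contacts.sort(key=lambda c: (c.atom_a, c.atom_b))
    return ContactSet(contacts)


# ---------------------------------------------------------------------------
# footprint summary

def summarize_footprint(
    contacts: ContactSet,
    cx: AnnotatedComplex,
    bsa: BsaBreakdown | None = None,
) -> pd.DataFrame:
    """Per-region footprint table: BSA share, contact counts by kind,
    peptide-vs-HLA partition, and the peptide pockets each region touches.

    Every region row is always present (zeros when untouched), so empty
    interfaces produce a complete table of zeros.
    """
    rows = {
        label: {
            "region": label,
            "bsa_pct": 0.0,
            "n_hbond": 0, "n_vdw": 0, "n_salt_bridge": 0, "n_disulfide": 0,
            "n_total": 0, "n_to_peptide": 0, "n_to_hla": 0,
            "pockets": set(),
        }
        for label in REGION_LABELS
    }
    if bsa is not None:
        for label in REGION_LABELS:
            rows[label]["bsa_pct"] = round(bsa.per_region_pct.get(label, 0.0), 1)

    res_by_key = {
        (res.chain_id, res.seq_id, res.icode): (role, res)
        for role in cx.chains
        for res in cx.chains[role]
    }
    for c in contacts:
        tcr_end, other_end = (
            (c.atom_a, c.atom_b) if c.role_a in TCR_SIDE else (c.atom_b, c.atom_a)
        )
        tcr_role = c.role_a if c.role_a in TCR_SIDE else c.role_b
        other_role = c.role_b if c.role_a in TCR_SIDE else c.role_a
        chain_id, _, seq_id, _ = tcr_end
        entry = res_by_key.get((chain_id, seq_id, ""))
        if entry is None:
            continue
        _, res = entry
        region = _region_of(cx, tcr_role, res)
        if region is None or region not in rows:
            continue
        row = rows[region]
        row["n_total"] += 1
        for kind in c.kinds:
            row[f"n_{kind}"] += 1
        if other_role == "peptide":
            row["n_to_peptide"] += 1
            if cx.register is not None:
                pocket = cx.register.pocket_of(other_end[2])
                if pocket:
                    row["pockets"].add(pocket)
        else:
            row["n_to_hla"] += 1

    def _pocket_sort(p: str):
        return (p == "flank", int(p[1:]) if p != "flank" else 0)

    records = []
    for label in REGION_LABELS:
        row = rows[label]
        row["pockets"] = ",".join(sorted(row["pockets"], key=_pocket_sort))
        records.append(row)
    return pd.DataFrame.from_records(records).set_index("region")


# ---------------------------------------------------------------------------
# docking geometry

@dataclass
class DockingGeometry:
    """TCR docking geometry over the peptide-binding groove."""

    v_alpha_centroid: np.ndarray
    v_beta_centroid: np.ndarray
    peptide_axis: np.ndarray  # unit vector, P-2 end -> P9 end
    docking_angle: float  # degrees in [0, 90]

    def to_dict(self) -> dict:
        return {
            "v_alpha_centroid": [round(float(x), 2) for x in self.v_alpha_centroid],
            "v_beta_centroid": [round(float(x), 2) for x in self.v_beta_centroid],
            "peptide_axis": [round(float(x), 4) for x in self.peptide_axis],
            "docking_angle_deg": round(self.docking_angle, 1),
        }


class GeometryError(ValueError):
    """Docking geometry requested on insufficient coordinates."""


def _calpha_coords(residues: list[Residue], seq_range=None) -> np.ndarray:
    pts = []
    for res in residues:
        if seq_range is not None and not (seq_range[0] <= res.seq_id <= seq_range[1]):
            continue
        ca = res.atom("CA")
        if ca is not None:
            pts.append(ca.coords)
    return np.array(pts) if pts else np.zeros((0, 3))


def docking_geometry(
    cx: AnnotatedComplex,
    v_domain_range: tuple[int, int] = (1, 129),
) -> DockingGeometry:
    """Docking angle of the TCR over the bound peptide.

    The angle is between the Valpha->Vbeta centroid vector (centroids
    over variable-domain C-alpha atoms) and the total-least-squares
    axis of the peptide C-alpha trace, folded to [0, 90] degrees so
    the convention is sign-free.
    """
    ca_alpha = _calpha_coords(cx.chains.get("tcr_alpha", []), v_domain_range)
    ca_beta = _calpha_coords(cx.chains.get("tcr_beta", []), v_domain_range)
    ca_pep = _calpha_coords(cx.chains.get("peptide", []))
    if len(ca_pep) < 5:
        raise GeometryError(f"need >= 5 peptide C-alpha atoms, got {len(ca_pep)}")
    if len(ca_alpha) == 0 or len(ca_beta) == 0:
        raise GeometryError("both TCR variable domains need C-alpha atoms")

    cen_a = ca_alpha.mean(axis=0)
    cen_b = ca_beta.mean(axis=0)
    u = cen_b - cen_a
    if np.linalg.norm(u) == 0:
        raise GeometryError("coincident variable-domain centroids")
    u = u / np.linalg.norm(u)

    centered = ca_pep - ca_pep.mean(axis=0)
    _, _, vt = np.linalg.svd(centered, full_matrices=False)
    axis = vt[0]
    # orient N-terminus -> C-terminus
    if np.dot(axis, ca_pep[-1] - ca_pep[0]) < 0:
        axis = -axis

    cosang = abs(float(np.dot(u, axis)))
    angle = float(np.degrees(np.arccos(np.clip(cosang, 0.0, 1.0))))
    return DockingGeometry(
        v_alpha_centroid=cen_a,
        v_beta_centroid=cen_b,
        peptide_axis=axis,
        docking_angle=angle,
    )


# ---------------------------------------------------------------------------
# superposition

@dataclass
class Superposition:
    """Optimal rigid-body superposition (Kabsch) of matched atom sets."""

    rotation: np.ndarray  # (3, 3), det = +1
    translation: np.ndarray  # (3,)
    rmsd: float
    n_atoms: int

    def apply(self, coords: np.ndarray) -> np.ndarray:
        return coords @ self.rotation.T + self.translation


def superpose(coords_ref: np.ndarray, coords_mov: np.ndarray) -> Superposition:
    """Least-squares superposition of ``coords_mov`` onto ``coords_ref``.

    Uses the SVD form of the Kabsch algorithm with the proper-rotation
    correction (no reflections). Raises on length mismatch; warns on
    rank-deficient (collinear) selections.
    """
    ref = np.asarray(coords_ref, dtype=float)
    mov = np.asarray(coords_mov, dtype=float)
    if ref.shape != mov.shape or ref.ndim != 2 or ref.shape[1] != 3:
        raise ValueError(
            f"matched (n, 3) coordinate sets required, got {ref.shape} vs {mov.shape}"
        )
    n = len(ref)
    if n < 3:
        raise ValueError("need at least 3 matched atoms")

    cen_ref = ref.mean(axis=0)
    cen_mov = mov.mean(axis=0)
    p = ref - cen_ref
    q = mov - cen_mov

    h = q.T @ p
    u, s, vt = np.linalg.svd(h)
    if s[1] < 1e-9 * max(s[0], 1.0):
        warnings.warn("rank-deficient (collinear) selection; rotation ill-determined",
                      stacklevel=2)
    d = np.sign(np.linalg.det(vt.T @ u.T))
    corr = np.diag([1.0, 1.0, d])
    rot = vt.T @ corr @ u.T
    trans = cen_ref - rot @ cen_mov
    diff = p - q @ rot.T
    rmsd = float(np.sqrt((diff**2).sum() / n))
    return Superposition(rotation=rot, translation=trans, rmsd=rmsd, n_atoms=n)


def match_calpha(
    residues_a: list[Residue],
    residues_b: list[Residue],
) -> tuple[np.ndarray, np.ndarray]:
    """Paired C-alpha coordinates for residues shared by two chains
    (matched on author seq_id + insertion code)."""
    ca_a = {r.key: r.atom("CA") for r in residues_a if r.atom("CA") is not None}
    ca_b = {r.key: r.atom("CA") for r in residues_b if r.atom("CA") is not None}
    shared = sorted(set(ca_a) & set(ca_b))
    if not shared:
        return np.zeros((0, 3)), np.zeros((0, 3))
    return (
        np.array([ca_a[k].coords for k in shared]),
        np.array([ca_b[k].coords for k in shared]),
    )
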