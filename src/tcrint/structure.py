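"""Structure parsing and biological annotation of TCR-pMHC-II complexes.

Reads mmCIF/PDB coordinates (via gemmi), resolves alternate locations,
assigns biological roles to chains (MHC-II alpha/beta, peptide, TCR
alpha/beta), labels TCR variable-domain residues with IMGT CDR/framework
regions, maps the peptide onto the MHC-II pocket register (P-2 ... P9),
and tests the MHC beta chain for the shared-epitope motif.

Modified residues are first-class citizens: citrulline (``CIR``), the
deiminated arginine central to anti-citrullinated-protein autoimmunity,
is retained at its position in the peptide chain and participates in all
downstream surface and contact computations.
"""

from __future__ import annotations

import hashlib
import json
import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping

import gemmi
import numpy as np

from .radii import DEFAULT_TABLE, vdw_radius

__all__ = [
    "Atom",
    "Residue",
    "AnnotatedComplex",
    "RegionAnnotation",
    "RegisterMap",
    "SEResult",
    "ParseError",
    "EmptyStructureError",
    "RoleError",
    "RegisterError",
    "CoverageError",
    "parse_structure",
    "write_pdb",
    "assign_chain_roles",
    "assign_imgt_regions",
    "assign_peptide_register",
    "detect_shared_epitope",
    "chain_sequence",
]

# ---------------------------------------------------------------------------
# constants

ROLES = ("tcr_alpha", "tcr_beta", "mhc_alpha", "mhc_beta", "peptide", "other")
TERNARY_ROLES = ("tcr_alpha", "tcr_beta", "mhc_alpha", "mhc_beta", "peptide")
APO_ROLES = ("tcr_alpha", "tcr_beta")

#: Shared-epitope pentapeptides at HLA-DRB1 beta-chain positions 70-74,
#: the dominant genetic risk motif for rheumatoid arthritis.
SE_MOTIFS = ("QKRAA", "QRRAA", "RRRAA")
SE_WINDOW = (70, 74)

#: IMGT unique-numbering CDR intervals (inclusive) for TCR variable domains.
DEFAULT_IMGT_RANGES: dict[str, tuple[int, int]] = {
    "CDR1": (27, 38),
    "CDR2": (56, 65),
    "CDR3": (105, 117),
}
VARIABLE_DOMAIN = (1, 129)

#: Default auto-detection bounds for a MHC-II-bound peptide chain
#: (the bound epitope including flanking residues is typically 12-16-mer).
PEPTIDE_LEN_RANGE = (9, 25)

AA3TO1 = {
    "ALA": "A", "ARG": "R", "ASN": "N", "ASP": "D", "CYS": "C",
    "GLN": "Q", "GLU": "E", "GLY": "G", "HIS": "H", "ILE": "I",
    "LEU": "L", "LYS": "K", "MET": "M", "PHE": "F", "PRO": "P",
    "SER": "S", "THR": "T", "TRP": "W", "TYR": "Y", "VAL": "V",
    "CIR": "X",  # citrulline: no canonical one-letter code
    "MSE": "M",
}
AA1TO3 = {v: k for k, v in AA3TO1.items() if k not in ("CIR", "MSE")}

_WATER_NAMES = {"HOH", "WAT", "DOD", "H2O"}


# ---------------------------------------------------------------------------
# errors

class ParseError(RuntimeError):
    """Structure file could not be read."""


class EmptyStructureError(ParseError):
    """File contained no polymer residues."""


class RoleError(ValueError):
    """Chain-role assignment inconsistent with the requested mode."""


class RegisterError(ValueError):
    """Peptide register anchor not found in the peptide chain."""


class CoverageError(ValueError):
    """Sequence window required for motif detection is incomplete."""


# ---------------------------------------------------------------------------
# domain types

@dataclass
class Atom:
    """A heavy (or hydrogen) atom with coordinates and an assigned radius.

    ``vdw_radius`` is 0 until assigned from a named radii table; surface
    code refuses to run on unassigned atoms.
    """

    name: str
    element: str
    coords: np.ndarray  # shape (3,), Angstrom
    occupancy: float = 1.0
    altloc: str = ""
    vdw_radius: float = 0.0

    def __post_init__(self) -> None:
        self.coords = np.asarray(self.coords, dtype=float)
        if not np.all(np.isfinite(self.coords)):
            raise ValueError(f"non-finite coordinates for atom {self.name}")
        if not 0 < self.occupancy <= 1:
            raise ValueError(
                f"occupancy {self.occupancy} outside (0, 1] for atom {self.name}"
            )

    @property
    def is_hydrogen(self) -> bool:
        return self.element.strip().upper() in ("H", "D")


@dataclass
class Residue:
    """One residue: 3-letter name (non-standard codes retained), author
    numbering, and its atoms."""

    name: str
    seq_id: int
    icode: str
    chain_id: str
    atoms: list[Atom] = field(default_factory=list)

    @property
    def key(self) -> tuple[int, str]:
        return (self.seq_id, self.icode)

    def atom(self, name: str) -> Atom | None:
        for a in self.atoms:
            if a.name == name:
                return a
        return None

    def heavy_atoms(self) -> list[Atom]:
        return [a for a in self.atoms if not a.is_hydrogen]

    @property
    def one_letter(self) -> str:
        return AA3TO1.get(self.name.upper(), "X")


@dataclass
class RegionAnnotation:
    """Per-residue CDR/framework labels for a TCR variable domain.

    ``labels`` maps (seq_id, icode) -> label in {CDR1, CDR2, CDR3, FW}.
    Constant-domain residues (seq_id beyond the variable domain) are
    deliberately unlabelled.
    """

    labels: dict[tuple[int, str], str]
    imgt_ranges: dict[str, tuple[int, int]]

    def label_of(self, seq_id: int, icode: str = "") -> str | None:
        return self.labels.get((seq_id, icode))


@dataclass
class RegisterMap:
    """Peptide residue -> MHC-II pocket label (P-2 ... P9, or flank)."""

    labels: dict[tuple[int, str], str]
    p1_residue: tuple[int, str]

    def pocket_of(self, seq_id: int, icode: str = "") -> str | None:
        return self.labels.get((seq_id, icode))


@dataclass
class SEResult:
    """Shared-epitope test outcome on the MHC beta chain 70-74 window."""

    positive: bool
    motif: str
    window: str


@dataclass
class AnnotatedComplex:
    """A parsed structure with chain roles and biological annotations.

    ``chains`` maps role -> residue list; ``regions`` maps TCR roles to
    their CDR/FW annotation; ``register`` is the peptide pocket map.
    ``hetero`` carries waters/ligands, which are flagged but excluded
    from every interface computation.
    """

    chains: dict[str, list[Residue]]
    regions: dict[str, RegionAnnotation] = field(default_factory=dict)
    register: RegisterMap | None = None
    hetero: dict[str, list[Residue]] = field(default_factory=dict)
    provenance: dict = field(default_factory=dict)

    def role_of_chain(self, chain_id: str) -> str | None:
        for role, residues in self.chains.items():
            if residues and residues[0].chain_id == chain_id:
                return role
        return None

    def residues(self, *roles: str) -> list[Residue]:
        out: list[Residue] = []
        for role in roles:
            out.extend(self.chains.get(role, []))
        return out

    def to_json(self) -> str:
        """Serialize the annotated model (without coordinates) to JSON."""
        doc = {
            "provenance": self.provenance,
            "chains": {
                role: {
                    "chain_id": res[0].chain_id if res else None,
                    "n_residues": len(res),
                    "sequence": "".join(r.one_letter for r in res),
                }
                for role, res in self.chains.items()
            },
            "regions": {
                role: {f"{k[0]}{k[1]}": v for k, v in ann.labels.items()}
                for role, ann in self.regions.items()
            },
            "register": (
                {f"{k[0]}{k[1]}": v for k, v in self.register.labels.items()}
                if self.register
                else None
            ),
        }
        return json.dumps(doc, indent=2, sort_keys=True)


# ---------------------------------------------------------------------------
# parsing

def _is_polymer_residue(res: gemmi.Residue) -> bool:
    name = res.name.upper()
    if name in _WATER_NAMES:
        return False
    info = gemmi.find_tabulated_residue(res.name)
    if info is not None and info.is_amino_acid():
        return True
    # unknown ligands lack the backbone; modified residues keep it
    names = {a.name for a in res}
    return "CA" in names and "N" in names


def _resolve_altlocs(atoms: list[Atom]) -> list[Atom]:
    """Keep one location per atom name: highest occupancy, ties -> 'A'."""
    by_name: dict[str, list[Atom]] = {}
    for a in atoms:
        by_name.setdefault(a.name, []).append(a)
    kept = []
    for group in by_name.values():
        group.sort(key=lambda a: (-a.occupancy, a.altloc or "A"))
        best = group[0]
        best.altloc = ""
        kept.append(best)
    return kept


def parse_structure(
    path: str | Path,
    *,
    radii_table: str | None = DEFAULT_TABLE,
) -> tuple[dict[str, list[Residue]], dict[str, list[Residue]]]:
    """Parse an mmCIF/PDB file into per-chain residue lists.

    Alternate locations are resolved by the highest-occupancy policy
    (ties broken toward altloc 'A'). Modified residues such as
    citrulline (CIR) are kept in sequence; waters and non-polymer
    ligands are returned separately in the second map.

    Parameters
    ----------
    path:
        mmCIF or PDB file.
    radii_table:
        Name of the van der Waals radii table to assign, or None to
        leave radii unassigned.

    Returns
    -------
    (polymer, hetero):
        Both map chain id -> list of :class:`Residue` in author order.
    """
    path = Path(path)
    try:
        st = gemmi.read_structure(str(path))
    except (RuntimeError, ValueError, OSError) as exc:
        raise ParseError(f"cannot parse structure file {path}: {exc}") from exc
    st.setup_entities()
    if len(st) == 0:
        raise EmptyStructureError(f"{path}: no models in file")

    model = st[0]
    polymer: dict[str, list[Residue]] = {}
    hetero: dict[str, list[Residue]] = {}
    for chain in model:
        for gres in chain:
            atoms = []
            for ga in gres:
                elem = ga.element.name if ga.element else ""
                atoms.append(
                    Atom(
                        name=ga.name,
                        element=elem,
                        coords=np.array([ga.pos.x, ga.pos.y, ga.pos.z]),
                        occupancy=min(max(ga.occ, 1e-6), 1.0),
                        altloc=ga.altloc if ga.altloc else "",
                    )
                )
            atoms = _resolve_altlocs(atoms)
            if radii_table is not None:
                for a in atoms:
                    a.vdw_radius = vdw_radius(a.element, radii_table)
            res = Residue(
                name=gres.name,
                seq_id=gres.seqid.num,
                icode=(gres.seqid.icode or "").strip(),
                chain_id=chain.name,
                atoms=atoms,
            )
            target = polymer if _is_polymer_residue(gres) else hetero
            target.setdefault(chain.name, []).append(res)

    if not any(polymer.values()):
        raise EmptyStructureError(f"{path}: file contains no polymer residues")
    return polymer, hetero


def write_pdb(chains: Mapping[str, list[Residue]], path: str | Path) -> None:
    """Write per-chain residue lists to a PDB file (round-trip stable)."""
    st = gemmi.Structure()
    st.name = "tcrint"
    model = gemmi.Model("1")
    for chain_id in chains:
        chain = gemmi.Chain(chain_id)
        for res in chains[chain_id]:
            gres = gemmi.Residue()
            gres.name = res.name
            gres.seqid = gemmi.SeqId(res.seq_id, res.icode or " ")
            gres.het_flag = "A" if res.name.upper() in AA1TO3.values() else "H"
            for a in res.atoms:
                ga = gemmi.Atom()
                ga.name = a.name
                ga.element = gemmi.Element(a.element)
                ga.pos = gemmi.Position(*a.coords)
                ga.occ = a.occupancy
                gres.add_atom(ga)
            chain.add_residue(gres)
        model.add_chain(chain)
    st.add_model(model)
    st.setup_entities()
    st.write_pdb(str(path))


def chain_sequence(residues: Iterable[Residue]) -> str:
    return "".join(r.one_letter for r in residues)


# ---------------------------------------------------------------------------
# chain roles

def assign_chain_roles(
    polymer: Mapping[str, list[Residue]],
    role_config: Mapping[str, str] | None = None,
    *,
    mode: str = "ternary",
    hetero: Mapping[str, list[Residue]] | None = None,
    provenance: Mapping | None = None,
) -> AnnotatedComplex:
    """Assign biological roles to chains.

    Roles are taken from ``role_config`` (chain id -> role). Any chain
    not named there whose length falls in the peptide auto-detection
    window (9-25 residues) is assigned ``peptide``; remaining chains
    become ``other``. Ternary mode requires all five roles; apo mode
    requires the two TCR roles.
    """
    if mode not in ("ternary", "apo"):
        raise ValueError(f"unknown mode {mode!r}")
    role_config = dict(role_config or {})

    assigned: dict[str, str] = {}
    for chain_id, role in role_config.items():
        if role not in ROLES:
            raise RoleError(f"unknown role {role!r} for chain {chain_id}")
        if chain_id not in polymer:
            raise RoleError(f"config names chain {chain_id!r} absent from structure")
        if role != "other" and role in assigned.values():
            raise RoleError(f"two chains mapped to role {role!r}")
        assigned[chain_id] = role

    lo, hi = PEPTIDE_LEN_RANGE
    for chain_id, residues in polymer.items():
        if chain_id in assigned:
            continue
        if "peptide" not in assigned.values() and lo <= len(residues) <= hi:
            assigned[chain_id] = "peptide"
        else:
            assigned[chain_id] = "other"

    required = TERNARY_ROLES if mode == "ternary" else APO_ROLES
    missing = [r for r in required if r not in assigned.values()]
    if missing:
        raise RoleError(
            f"{mode} mode requires roles {list(required)}; missing {missing}"
        )

    chains: dict[str, list[Residue]] = {}
    for chain_id, role in assigned.items():
        if role == "other":
            chains.setdefault("other", []).extend(polymer[chain_id])
        else:
            chains[role] = list(polymer[chain_id])

    if mode == "ternary" and len(chains["peptide"]) < 8:
        raise RoleError(
            f"peptide chain has {len(chains['peptide'])} residues; need >= 8"
        )

    return AnnotatedComplex(
        chains=chains,
        hetero=dict(hetero or {}),
        provenance=dict(provenance or {}),
    )


# ---------------------------------------------------------------------------
# IMGT regions

def assign_imgt_regions(
    tcr_chain: list[Residue],
    imgt_ranges: Mapping[str, tuple[int, int]] | None = None,
) -> RegionAnnotation:
    """Label each variable-domain residue CDR1/CDR2/CDR3/FW.

    Assumes the deposited coordinates already follow IMGT unique
    numbering (variable domain 1-129). Residues numbered beyond the
    variable domain belong to the constant domain and are left
    unlabelled. Intervals are inclusive and must not overlap.
    """
    ranges = dict(imgt_ranges or DEFAULT_IMGT_RANGES)
    spans = sorted(ranges.items(), key=lambda kv: kv[1][0])
    for (_, (a_lo, a_hi)), (_, (b_lo, b_hi)) in zip(spans, spans[1:]):
        if b_lo <= a_hi:
            raise ValueError(f"overlapping IMGT intervals: {spans}")

    v_lo, v_hi = VARIABLE_DOMAIN
    labels: dict[tuple[int, str], str] = {}
    for res in tcr_chain:
        if res.seq_id > v_hi:
            continue  # constant domain
        if res.seq_id < v_lo:
            warnings.warn(
                f"residue {res.chain_id}:{res.seq_id} below the variable domain; "
                "labelled FW",
                stacklevel=2,
            )
            labels[res.key] = "FW"
            continue
        label = "FW"
        for name, (lo, hi) in ranges.items():
            if lo <= res.seq_id <= hi:
                label = name
                break
        labels[res.key] = label
    return RegionAnnotation(labels=labels, imgt_ranges=ranges)


# ---------------------------------------------------------------------------
# peptide register

def assign_peptide_register(
    peptide_chain: list[Residue],
    p1_seq_id: int,
    p1_icode: str = "",
) -> RegisterMap:
    """Map peptide residues onto MHC-II pockets anchored at P1.

    Residues one and two positions upstream of P1 get P-1/P-2;
    downstream residues get P2..P9; anything beyond the canonical
    P-2..P9 groove span (e.g. solubility-tag lysines) is ``flank``.
    """
    keys = [r.key for r in peptide_chain]
    anchor = (p1_seq_id, p1_icode)
    if anchor not in keys:
        raise RegisterError(
            f"P1 anchor residue {p1_seq_id}{p1_icode!r} not found in peptide chain"
        )
    i1 = keys.index(anchor)
    labels: dict[tuple[int, str], str] = {}
    for i, key in enumerate(keys):
        offset = i - i1
        pocket = offset + 1 if offset >= 0 else offset
        labels[key] = f"P{pocket}" if -2 <= pocket <= 9 and pocket != 0 else "flank"
    return RegisterMap(labels=labels, p1_residue=anchor)


# ---------------------------------------------------------------------------
# shared epitope

def detect_shared_epitope(
    mhc_beta_sequence: str,
    numbering_offset: int = 1,
) -> SEResult:
    """Test the MHC-II beta chain for the shared-epitope motif.

    The pentapeptide at mature-chain positions 70-74 is compared
    (case-insensitively) against QKRAA, QRRAA and RRRAA.

    Parameters
    ----------
    mhc_beta_sequence:
        One-letter sequence of the beta chain.
    numbering_offset:
        Mature-chain position of the first sequence character
        (1 when the sequence starts at residue 1).
    """
    lo, hi = SE_WINDOW
    start = lo - numbering_offset
    stop = hi - numbering_offset + 1
    if start < 0 or stop > len(mhc_beta_sequence):
        raise CoverageError(
            f"sequence does not cover beta-chain positions {lo}-{hi} "
            f"(offset {numbering_offset}, length {len(mhc_beta_sequence)})"
        )
    window = mhc_beta_sequence[start:stop].upper()
    positive = window in SE_MOTIFS
    return SEResult(positive=positive, motif=window if positive else "", window=window)


def config_digest(obj) -> str:
    """Stable short digest of a JSON-serializable configuration object."""
    payload = json.dumps(obj, sort_keys=True, default=str).encode()
    return hashlib.sha256(payload).hexdigest()[:12]
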