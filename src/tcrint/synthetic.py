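"""Synthetic fixtures with bundled ground truth.

Everything the test suite and the analysis drivers need is generated
here, deterministically under a seed:

* sphere clusters whose solvent-accessible and buried areas have exact
  closed forms (isolated sphere, two-sphere spherical cap);
* a miniature five-chain "complex" — two MHC-II-like chains carrying a
  shared-epitope window, a 12-mer epitope with citrulline at pocket
  P-1, and two TCR-like chains — whose contact inventory, pocket
  register and docking angle are known by construction;
* simulated steady-state SPR and fluorescence-polarization competition
  curves drawn from the same models the fitting code estimates.

The geometry of the toy complex is deliberately schematic: atoms are
placed to realize an exact planted contact list, not to resemble real
protein stereochemistry (that is a non-goal).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .binding import BindingCurve, CompetitionCurve, four_pl, one_site
from .radii import vdw_radius
from .structure import AA1TO3, AnnotatedComplex, Atom, Residue

__all__ = [
    "SphereClusterSpec",
    "ToyComplexSpec",
    "SprSimSpec",
    "FpSimSpec",
    "isolated_sphere_area",
    "two_sphere_buried_area",
    "make_sphere_cluster",
    "two_sphere_complex",
    "make_toy_complex",
    "simulate_spr",
    "simulate_fp",
]


# ---------------------------------------------------------------------------
# closed-form oracles

def isolated_sphere_area(radius: float, probe: float) -> float:
    """SASA of an isolated atom: the full expanded sphere, 4*pi*(r+p)^2."""
    return 4.0 * np.pi * (radius + probe) ** 2


def two_sphere_buried_area(
    r1: float, r2: float, d: float, probe: float
) -> tuple[float, float]:
    """Exact buried area on each of two overlapping expanded spheres.

    With expanded radii R_i = r_i + probe and center distance d, the
    part of sphere 1 inside sphere 2 is a spherical cap of height
    h1 = R1 - (d^2 + R1^2 - R2^2) / (2 d), with area 2*pi*R1*h1
    (and symmetrically for sphere 2). Zero when the expanded spheres
    do not overlap; an error when one sphere engulfs the other.
    """
    R1, R2 = r1 + probe, r2 + probe
    if d <= 0:
        raise ValueError("center distance must be positive")
    if d >= R1 + R2:
        return 0.0, 0.0
    if d <= abs(R1 - R2):
        raise ValueError("one expanded sphere engulfs the other")
    h1 = R1 - (d * d + R1 * R1 - R2 * R2) / (2.0 * d)
    h2 = R2 - (d * d + R2 * R2 - R1 * R1) / (2.0 * d)
    return 2.0 * np.pi * R1 * h1, 2.0 * np.pi * R2 * h2


# ---------------------------------------------------------------------------
# sphere clusters

@dataclass
class SphereClusterSpec:
    """A cluster of single-atom 'residues' with analytic surface truth."""

    centers: np.ndarray  # (n, 3)
    radius: float = 1.7
    probe: float = 1.4
    element: str = "C"

    def __post_init__(self) -> None:
        self.centers = np.atleast_2d(np.asarray(self.centers, dtype=float))


def _sphere_atom(center, element: str, radius: float) -> Atom:
    return Atom(name=element.upper(), element=element, coords=np.asarray(center),
                vdw_radius=radius)


def make_sphere_cluster(
    spec: SphereClusterSpec,
) -> tuple[list[Residue], np.ndarray]:
    """Build single-atom residues plus their exact expected SASA.

    The expected per-atom SASA treats occlusion pairwise by the
    spherical-cap formula; it is exact whenever no point of a sphere is
    occluded by two neighbors at once (the regime all shipped fixtures
    stay in), and an error is raised on engulfing overlaps.
    """
    n = len(spec.centers)
    residues = [
        Residue(
            name="SPH", seq_id=i + 1, icode="", chain_id="X",
            atoms=[_sphere_atom(c, spec.element, spec.radius)],
        )
        for i, c in enumerate(spec.centers)
    ]
    expected = np.full(n, isolated_sphere_area(spec.radius, spec.probe))
    for i in range(n):
        for j in range(i + 1, n):
            d = float(np.linalg.norm(spec.centers[i] - spec.centers[j]))
            a_i, a_j = two_sphere_buried_area(spec.radius, spec.radius, d, spec.probe)
            expected[i] -= a_i
            expected[j] -= a_j
    return residues, expected


def two_sphere_complex(
    d: float, radius: float = 1.7, element: str = "C"
) -> tuple[AnnotatedComplex, float]:
    """Two single-atom chains at distance ``d`` plus the exact two-sided
    buried area of their interface (for a given probe, use the matching
    SasaParams downstream with probe 1.4)."""
    probe = 1.4
    r1 = Residue(name="SPH", seq_id=1, icode="", chain_id="A",
                 atoms=[_sphere_atom([0.0, 0.0, 0.0], element, radius)])
    r2 = Residue(name="SPH", seq_id=1, icode="", chain_id="B",
                 atoms=[_sphere_atom([d, 0.0, 0.0], element, radius)])
    cx = AnnotatedComplex(chains={"tcr_alpha": [r1], "mhc_alpha": [r2]})
    if d >= 2 * (radius + probe):
        expected = 0.0
    else:
        a1, a2 = two_sphere_buried_area(radius, radius, d, probe)
        expected = a1 + a2
    return cx, expected


# ---------------------------------------------------------------------------
# toy five-chain complex

#: epitope layout of the toy: a 12-mer numbered 1013-1024 with citrulline
#: (CIR) at the P-1 and P2 pockets and P1 anchored at Tyr 1015
TOY_PEPTIDE = [
    (1013, "ASP"), (1014, "CIR"), (1015, "TYR"), (1016, "CIR"),
    (1017, "LEU"), (1018, "ASN"), (1019, "TYR"), (1020, "SER"),
    (1021, "LEU"), (1022, "PRO"), (1023, "THR"), (1024, "GLY"),
]
TOY_P1_SEQ_ID = 1015


@dataclass
class ToyComplexSpec:
    """Specification of the miniature five-chain fixture.

    separation: height (A) of the TCR chains above the peptide plane.
    displacement: extra rigid offset of the whole TCR side (50 A makes
    every inter-side contact vanish).
    docking_angle_deg: planted angle between the Valpha->Vbeta centroid
    vector and the peptide axis.
    flank_lysines: append two C-terminal solubility lysines (flank).
    """

    separation: float = 12.0
    displacement: float = 0.0
    docking_angle_deg: float = 70.0
    flank_lysines: bool = False
    seed: int = 0

    def __post_init__(self) -> None:
        if self.separation <= 0:
            raise ValueError("separation must be positive")
        if not 0.0 <= self.docking_angle_deg <= 90.0:
            raise ValueError("docking_angle_deg must lie in [0, 90]")


@dataclass
class ToyGroundTruth:
    """Planted truth bundled with the toy complex."""

    contacts: list[tuple]  # (atom_a, atom_b, distance, kinds)
    docking_angle_deg: float
    register: dict[int, str]
    p1_seq_id: int
    se_motif: str
    se_positive: bool


def _mk_res(name3: str, seq_id: int, chain_id: str, base: np.ndarray,
            extra_atoms: list[Atom] | None = None) -> Residue:
    base = np.asarray(base, dtype=float)
    atoms = [
        Atom("N", "N", base + [-1.2, 0.8, 0.0], vdw_radius=vdw_radius("N")),
        Atom("CA", "C", base, vdw_radius=vdw_radius("C")),
        Atom("O", "O", base + [1.2, 0.8, 0.0], vdw_radius=vdw_radius("O")),
    ]
    if extra_atoms:
        atoms.extend(extra_atoms)
    return Residue(name=name3, seq_id=seq_id, icode="", chain_id=chain_id,
                   atoms=atoms)


def _chain_on_line(
    names_and_ids: list[tuple[int, str]], chain_id: str,
    centroid: np.ndarray, direction: np.ndarray, spacing: float = 1.2,
) -> list[Residue]:
    """Residues whose CA positions average exactly to ``centroid``."""
    n = len(names_and_ids)
    out = []
    for i, (seq_id, name3) in enumerate(names_and_ids):
        offset = (i - (n - 1) / 2.0) * spacing
        out.append(_mk_res(name3, seq_id, chain_id,
                           centroid + offset * np.asarray(direction, float)))
    return out


def make_toy_complex(
    spec: ToyComplexSpec | None = None,
) -> tuple[AnnotatedComplex, ToyGroundTruth]:
    """Build the miniature complex and its planted ground truth.

    Chains: A = MHC alpha-like, B = MHC beta-like (with the QKRAA
    shared-epitope window at 70-74), C = peptide (CIR at P-1 and P2),
    D = TCR alpha-like, E = TCR beta-like. Four contacts are planted
    across the interface — a backbone hydrogen bond to the P-1
    citrulline, a carbon-carbon van der Waals pair near P5, a
    lysine-glutamate salt bridge and a long disulfide — and every other
    inter-side atom pair is kept beyond the 4.5 A maximum cutoff.
    """
    spec = spec or ToyComplexSpec()
    theta = np.radians(spec.docking_angle_deg)
    shift = np.array([0.0, 0.0, spec.displacement])

    # peptide along +x at z = 0, CA spacing 3.8 A
    pep_entries = list(TOY_PEPTIDE)
    if spec.flank_lysines:
        pep_entries += [(1025, "LYS"), (1026, "LYS")]
    peptide = []
    for i, (seq_id, name3) in enumerate(pep_entries):
        base = np.array([3.8 * i, 0.0, 0.0])
        extra = []
        if seq_id == 1014:  # P-1 citrulline carries the planted H-bond acceptor
            extra.append(Atom("O7", "O", base + [0.0, 3.5, 0.0],
                              vdw_radius=vdw_radius("O")))
        peptide.append(_mk_res(name3, seq_id, "C", base, extra))

    # MHC-like platform chains below the peptide
    mhc_a_ids = [(sid, "ALA") for sid in range(50, 66)]
    mhc_a = _chain_on_line(mhc_a_ids, "A", np.array([20.0, -8.0, -6.0]),
                           np.array([1.0, 0.0, 0.0]), spacing=3.0)
    # planted salt-bridge partner: Glu 55 side-chain oxygen near the surface
    glu55 = next(r for r in mhc_a if r.seq_id == 55)
    glu55.name = "GLU"
    glu55.atoms.append(Atom("OE1", "O", np.array([30.0, 6.0, 0.0]),
                            vdw_radius=vdw_radius("O")))

    se_seq = "AAAAA" + "QKRAA" + "AAAAA" + "C"  # positions 65..80
    mhc_b_ids = [(65 + i, AA1TO3.get(c, "ALA")) for i, c in enumerate(se_seq)]
    mhc_b = _chain_on_line(mhc_b_ids, "B", np.array([20.0, 8.0, -6.0]),
                           np.array([1.0, 0.0, 0.0]), spacing=3.0)
    cys80 = next(r for r in mhc_b if r.seq_id == 80)
    cys80.atoms.append(Atom("SG", "S", np.array([-6.0, 0.0, 0.0]),
                            vdw_radius=vdw_radius("S")))

    # TCR-like chains: centroids realize the requested docking angle
    pep_axis = np.array([1.0, 0.0, 0.0])
    v = np.array([np.cos(theta), np.sin(theta), 0.0])
    mid = np.array([19.0, 0.0, spec.separation])
    cen_alpha = mid - 5.0 * v
    cen_beta = mid + 5.0 * v

    tcr_a_ids = [
        (20, "CYS"), (27, "GLY"), (28, "SER"), (57, "TYR"), (58, "LYS"),
        (105, "ALA"), (109, "VAL"), (110, "GLY"), (111, "ASN"), (112, "THR"),
        (113, "ASN"), (117, "GLY"),
    ]
    tcr_a = _chain_on_line(tcr_a_ids, "D", cen_alpha, np.array([0.0, 0.0, 1.0]))
    # planted backbone-like H-bond donor over the P-1 citrulline acceptor
    asn113 = next(r for r in tcr_a if r.seq_id == 113)
    asn113.atoms.append(Atom("N7", "N", np.array([3.8, 3.5, 3.4]) + shift,
                             vdw_radius=vdw_radius("N")))
    cys20 = next(r for r in tcr_a if r.seq_id == 20)
    cys20.atoms.append(Atom("SG", "S", np.array([-6.0, 0.0, 4.2]) + shift,
                            vdw_radius=vdw_radius("S")))

    tcr_b_ids = [
        (22, "GLY"), (30, "SER"), (31, "THR"), (57, "LYS"), (58, "GLY"),
        (105, "ALA"), (107, "ALA"), (110, "GLY"), (115, "SER"), (117, "GLY"),
    ]
    tcr_b = _chain_on_line(tcr_b_ids, "E", cen_beta, np.array([0.0, 0.0, 1.0]))
    ala107 = next(r for r in tcr_b if r.seq_id == 107)
    ala107.atoms.append(Atom("CB", "C", np.array([3.8 * 6, 0.0, 3.9]) + shift,
                             vdw_radius=vdw_radius("C")))
    lys57 = next(r for r in tcr_b if r.seq_id == 57)
    lys57.atoms.append(Atom("NZ", "N", np.array([30.0, 6.0, 3.0]) + shift,
                            vdw_radius=vdw_radius("N")))

    # apply the rigid displacement to the whole TCR side
    for res in tcr_a + tcr_b:
        for atom in res.atoms:
            if atom.name not in ("N7", "SG", "CB", "NZ"):
                atom.coords = atom.coords + shift

    cx = AnnotatedComplex(
        chains={
            "mhc_alpha": mhc_a, "mhc_beta": mhc_b, "peptide": peptide,
            "tcr_alpha": tcr_a, "tcr_beta": tcr_b,
        },
        provenance={"generator": "make_toy_complex", "spec": vars(spec)},
    )

    displaced = spec.displacement > 10.0
    planted = [] if displaced else [
        (("D", "ASN", 113, "N7"), ("C", "CIR", 1014, "O7"), 3.4,
         ("hbond", "vdw")),
        (("D", "CYS", 20, "SG"), ("B", "CYS", 80, "SG"), 4.2,
         ("disulfide",)),
        (("E", "ALA", 107, "CB"), ("C", "TYR", 1019, "CA"), 3.9,
         ("vdw",)),
        (("E", "LYS", 57, "NZ"), ("A", "GLU", 55, "OE1"), 3.0,
         ("salt_bridge", "hbond", "vdw")),
    ]

    register = {1013: "P-2", 1014: "P-1", 1015: "P1", 1016: "P2",
                1017: "P3", 1018: "P4", 1019: "P5", 1020: "P6",
                1021: "P7", 1022: "P8", 1023: "P9", 1024: "flank"}
    if spec.flank_lysines:
        register.update({1025: "flank", 1026: "flank"})

    truth = ToyGroundTruth(
        contacts=planted,
        docking_angle_deg=spec.docking_angle_deg,
        register=register,
        p1_seq_id=TOY_P1_SEQ_ID,
        se_motif="QKRAA",
        se_positive=True,
    )
    return cx, truth


# ---------------------------------------------------------------------------
# simulated binding experiments

@dataclass
class SprSimSpec:
    """Design of a simulated steady-state SPR experiment.

    Defaults mirror the characterization protocol: a 10-point twofold
    dilution series from 200 uM run in duplicate, Rmax 100 RU, additive
    Gaussian noise of 2 RU on each equilibrium response.
    """

    kd: float
    rmax: float = 100.0
    top_conc: float = 200.0
    dilution_factor: float = 2.0
    n_points: int = 10
    noise_sd: float = 2.0
    n_replicates: int = 2
    seed: int = 0

    def __post_init__(self) -> None:
        if min(self.kd, self.rmax, self.top_conc, self.dilution_factor) <= 0:
            raise ValueError("kd, rmax, top_conc, dilution_factor must be positive")
        if self.noise_sd < 0:
            raise ValueError("noise_sd must be >= 0")
        lowest = self.top_conc / self.dilution_factor ** (self.n_points - 1)
        if not lowest < self.kd < self.top_conc:
            import warnings
            warnings.warn(
                f"concentration series [{lowest:.3g}, {self.top_conc:g}] does not "
                f"bracket K_D = {self.kd:g} uM", stacklevel=2,
            )


@dataclass
class FpSimSpec:
    """Design of a simulated FP competition experiment.

    Defaults mirror the competition protocol: a 12-point threefold
    dilution from 500 uM in triplicate (spanning ~0.003-500 uM so both
    plateaus of a low-micromolar IC50 are covered), a four-parameter
    logistic with hill 1 between 100% and 0% binding, 3% Gaussian noise.
    """

    ic50: float
    hill: float = 1.0
    top: float = 100.0
    bottom: float = 0.0
    top_conc: float = 500.0
    dilution_factor: float = 3.0
    n_points: int = 12
    noise_sd: float = 3.0
    n_replicates: int = 3
    seed: int = 0

    def __post_init__(self) -> None:
        if self.ic50 <= 0:
            raise ValueError("ic50 must be positive")
        if self.top <= self.bottom:
            raise ValueError("top must exceed bottom")


def _dilution_series(top: float, factor: float, n: int) -> np.ndarray:
    return top / factor ** np.arange(n, dtype=float)


def simulate_spr(spec: SprSimSpec) -> BindingCurve:
    """Simulate equilibrium SPR responses from the one-site isotherm."""
    rng = np.random.default_rng(spec.seed)
    conc = _dilution_series(spec.top_conc, spec.dilution_factor, spec.n_points)
    concs, resps, reps = [], [], []
    for rep in range(spec.n_replicates):
        noise = (rng.normal(0.0, spec.noise_sd, size=len(conc))
                 if spec.noise_sd > 0 else np.zeros(len(conc)))
        concs.append(conc)
        resps.append(one_site(conc, spec.kd, spec.rmax) + noise)
        reps.append(np.full(len(conc), rep))
    return BindingCurve(
        np.concatenate(concs), np.concatenate(resps), np.concatenate(reps)
    )


def simulate_fp(spec: FpSimSpec) -> CompetitionCurve:
    """Simulate normalized competition binding from the 4PL model."""
    rng = np.random.default_rng(spec.seed)
    conc = _dilution_series(spec.top_conc, spec.dilution_factor, spec.n_points)
    concs, ys, reps = [], [], []
    for rep in range(spec.n_replicates):
        noise = (rng.normal(0.0, spec.noise_sd, size=len(conc))
                 if spec.noise_sd > 0 else np.zeros(len(conc)))
        concs.append(conc)
        ys.append(four_pl(conc, spec.ic50, spec.hill, spec.top, spec.bottom) + noise)
        reps.append(np.full(len(conc), rep))
    return CompetitionCurve(
        np.concatenate(concs), np.concatenate(ys), np.concatenate(reps)
    )
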