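"""Report bundles: orchestrate the analysis stages and write results.

Outputs are deterministic for identical config + inputs: keys sorted,
floats written at fixed precision (1 decimal for areas and percentages,
2 for distances, 3 significant figures for micromolar quantities), and
every file carries the config digest and package version.
"""

from __future__ import annotations

import json
import logging
from pathlib import Path

from . import __version__
from .binding import (
    classify_impact,
    fit_competition,
    fit_steady_state,
    read_binding_csv,
    read_competition_csv,
)
from .config import BindingConfig, InterfaceConfig
from .interface import (
    ContactCriteria,
    compute_bsa,
    detect_contacts,
    docking_geometry,
    match_calpha,
    summarize_footprint,
    superpose,
)
from .sasa import SasaParams
from .structure import (
    assign_chain_roles,
    assign_imgt_regions,
    assign_peptide_register,
    chain_sequence,
    config_digest,
    detect_shared_epitope,
    parse_structure,
)

log = logging.getLogger("tcrint")


def _provenance(config) -> dict:
    # out_dir and verbosity do not affect any computed number
    payload = config.model_dump(mode="json", exclude={"out_dir", "verbosity"})
    return {
        "tool": "tcrint",
        "version": __version__,
        "config_digest": config_digest(payload),
    }


def _write_json(path: Path, payload: dict, provenance: dict) -> None:
    doc = {"provenance": provenance, **payload}
    path.write_text(json.dumps(doc, indent=2, sort_keys=True) + "\n")


def annotate(config: InterfaceConfig):
    """Parse + annotate the structure named by the config."""
    polymer, hetero = parse_structure(
        config.structure, radii_table=config.sasa.radii_table
    )
    cx = assign_chain_roles(
        polymer, config.chain_roles, mode=config.mode, hetero=hetero,
        provenance={"source": str(config.structure)},
    )
    for role in ("tcr_alpha", "tcr_beta"):
        if role in cx.chains:
            cx.regions[role] = assign_imgt_regions(
                cx.chains[role], config.imgt_ranges
            )
    if config.mode == "ternary" and config.p1_seq_id is not None:
        cx.register = assign_peptide_register(
            cx.chains["peptide"], config.p1_seq_id
        )
    return cx


def run_interface(config: InterfaceConfig) -> dict:
    """Run the structural stages and write the report bundle.

    Ternary mode: BSA breakdown, contact table, footprint table,
    docking geometry, shared-epitope call and a text summary.
    Apo mode (with a holo reference): TCR C-alpha superposition r.m.s.d.
    Returns the bundle as a dict of output paths and headline numbers.
    """
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    prov = _provenance(config)

    log.info("parsing %s", config.structure)
    cx = annotate(config)

    if config.mode == "apo":
        if config.reference is None:
            raise ValueError("apo mode needs a holo reference structure")
        ref_cfg = config.model_copy(update={"structure": config.reference})
        log.info("parsing holo reference %s", config.reference)
        ref = annotate(ref_cfg)
        pairs_ref, pairs_mov = [], []
        for role in ("tcr_alpha", "tcr_beta"):
            a, b = match_calpha(ref.chains.get(role, []), cx.chains.get(role, []))
            pairs_ref.append(a)
            pairs_mov.append(b)
        import numpy as np

        coords_ref = np.vstack(pairs_ref)
        coords_mov = np.vstack(pairs_mov)
        sup = superpose(coords_ref, coords_mov)
        payload = {
            "rmsd_A": round(sup.rmsd, 2),
            "n_calpha": sup.n_atoms,
        }
        _write_json(out / "superposition.json", payload, prov)
        summary = (
            f"tcrint v{__version__} (config {prov['config_digest']})\n"
            f"apo-vs-holo TCR C-alpha superposition: "
            f"r.m.s.d. {sup.rmsd:.2f} A over {sup.n_atoms} atoms\n"
        )
        (out / "summary.txt").write_text(summary)
        return {"rmsd": sup.rmsd, "out_dir": str(out)}

    # ternary mode ---------------------------------------------------------
    log.info("buried surface area")
    params = SasaParams(
        probe_radius=config.sasa.probe_radius,
        n_points=config.sasa.n_points,
        radii_table=config.sasa.radii_table,
    )
    bsa = compute_bsa(cx, params)
    log.info("contacts")
    crit = ContactCriteria(**config.contacts.model_dump())
    contacts = detect_contacts(cx, crit)
    footprint = summarize_footprint(contacts, cx, bsa)
    log.info("docking geometry")
    geometry = docking_geometry(cx)

    beta = cx.chains["mhc_beta"]
    se = detect_shared_epitope(chain_sequence(beta), beta[0].seq_id)

    _write_json(out / "bsa.json", bsa.to_dict(), prov)
    _write_json(out / "geometry.json", geometry.to_dict(), prov)
    _write_json(
        out / "shared_epitope.json",
        {"positive": se.positive, "motif": se.motif, "window": se.window},
        prov,
    )
    contacts.to_tsv(out / "contacts.tsv")
    footprint.to_csv(out / "footprint.tsv", sep="\t")
    (out / "annotated.json").write_text(cx.to_json() + "\n")

    share = bsa.chain_share_pct
    loop_pct = bsa.per_region_pct
    summary = [
        f"tcrint v{__version__} (config {prov['config_digest']})",
        f"total interface BSA: {bsa.total_bsa:.1f} A^2 "
        f"(TCR side {bsa.tcr_side_bsa:.1f}, pMHC side {bsa.pmhc_side_bsa:.1f})",
        f"TCR chain share: alpha {share['alpha']:.1f}% / beta {share['beta']:.1f}%",
        "per-region share of TCR-side BSA: "
        + ", ".join(f"{k} {v:.1f}%" for k, v in sorted(loop_pct.items())),
        f"docking angle: {geometry.docking_angle:.1f} deg",
        f"contacts: {len(contacts)} total "
        f"({len(contacts.of_kind('hbond'))} H-bond, "
        f"{len(contacts.of_kind('salt_bridge'))} salt bridge, "
        f"{len(contacts.of_kind('disulfide'))} disulfide)",
        f"shared epitope (beta 70-74 = {se.window}): "
        + ("positive, motif " + se.motif if se.positive else "negative"),
    ]
    (out / "summary.txt").write_text("\n".join(summary) + "\n")
    for line in summary:
        log.info("%s", line)

    return {
        "total_bsa": bsa.total_bsa,
        "chain_share_pct": share,
        "per_region_pct": loop_pct,
        "docking_angle": geometry.docking_angle,
        "n_contacts": len(contacts),
        "se_positive": se.positive,
        "out_dir": str(out),
    }


def run_binding(config: BindingConfig) -> dict:
    """Fit every curve in the config and write the fit tables.

    SPR assay: one-site K_D fits; when a wild-type label is given, a
    fold-change impact class is attached to every other curve.
    FP assay: 4PL IC50 fits, with unbounded curves reported as
    "> max tested".
    """
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    prov = _provenance(config)

    results: dict[str, dict] = {}
    if config.assay == "spr":
        fits = {}
        for label in sorted(config.curves):
            curve = read_binding_csv(config.curves[label])
            fits[label] = fit_steady_state(curve, pooled=config.pooled)
            results[label] = fits[label].to_dict()
            log.info("%s: K_D = %.3g uM (+/- %.2g)", label,
                     fits[label].kd, fits[label].se_kd)
        if config.wildtype is not None:
            if config.wildtype not in fits:
                raise ValueError(
                    f"wild-type label {config.wildtype!r} not among curves"
                )
            kd_wt = fits[config.wildtype].kd
            for label, fit in fits.items():
                impact = classify_impact(fit.kd, kd_wt)
                results[label]["fold_vs_wildtype"] = float(f"{impact.fold:.3g}")
                results[label]["impact"] = impact.label
                if impact.note:
                    results[label]["impact_note"] = impact.note
        _write_json(out / "kd_fits.json", {"fits": results}, prov)
    else:
        for label in sorted(config.curves):
            curve = read_competition_csv(config.curves[label])
            fit = fit_competition(curve, residual_floor=config.residual_floor)
            results[label] = fit.to_dict()
            log.info("%s: IC50 = %s uM", label, results[label]["ic50_uM"])
        _write_json(out / "ic50_fits.json", {"fits": results}, prov)

    return {"fits": results, "out_dir": str(out)}
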