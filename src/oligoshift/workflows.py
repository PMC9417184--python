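"""End-to-end workflows: oligomeric-state classification from a scattering
profile, and the dimer-to-hexamer design screen from a candidate subunit
plus a template assembly.  Each workflow writes a JSON report embedding the
tool version, configuration snapshot, seeds, and input checksums.
"""

from __future__ import annotations

import hashlib
import json
from pathlib import Path

from . import __version__
from .config import RunConfig
from .design import (MutationSite, ScoreWeights, ScreenReport, run_screen)
from .interface import _aligned_columns, differing_interface_sites
from .saxs import OligomericCall, SAXSProfile, classify_oligomer, guinier_fit
from .structure import AssemblyModel, chain_sequence, read_pdb, write_pdb
from .symmetry import derive_symmetry, superpose


def _sha256(path: str | Path) -> str:
    return hashlib.sha256(Path(path).read_bytes()).hexdigest()


def _report_header(config: RunConfig, inputs: dict[str, str | Path]) -> dict:
    return {
        "tool": "oligoshift",
        "version": __version__,
        "config": config.to_dict(),
        "inputs": {name: {"path": str(p), "sha256": _sha256(p)}
                   for name, p in inputs.items()},
    }


def run_classify_workflow(config: RunConfig, data_path: str | Path,
                          model_paths: dict[str, str | Path],
                          out_dir: str | Path,
                          measured_mass: float | None = None,
                          subunit_mass: float | None = None) -> OligomericCall:
    """Guinier analysis plus chi-based model selection among candidates.

    Writes ``classify_report.json`` and a plot-ready ``residuals.tsv`` into
    ``out_dir`` and returns the call.
    """
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    profile = SAXSProfile.read_dat(data_path, label="experimental")
    guinier = guinier_fit(profile, config.qrg_limit)
    candidates = {label: read_pdb(p) for label, p in model_paths.items()}
    call = classify_oligomer(profile, candidates, measured_mass, subunit_mass,
                             config.granularity)

    report = _report_header(config, {"data": data_path, **model_paths})
    report["guinier"] = guinier.to_dict()
    report["call"] = call.to_dict()
    (out_dir / "classify_report.json").write_text(
        json.dumps(report, indent=2, sort_keys=True) + "\n")

    labels = sorted(call.fits)
    lines = ["q\t" + "\t".join(f"residual_{label}" for label in labels)]
    fit0 = call.fits[labels[0]]
    for i, q in enumerate(fit0.q):
        row = [f"{q:.6f}"] + [f"{call.fits[lb].residuals[i]:.6f}" for lb in labels]
        lines.append("\t".join(row))
    (out_dir / "residuals.tsv").write_text("\n".join(lines) + "\n")
    return call


def _map_positions(template_seq: str, subunit_seq: str,
                   template_positions: list[int],
                   template_ids: list[int], subunit_ids: list[int]) -> dict[int, int]:
    """Template residue number -> subunit residue number via alignment."""
    mapping = {}
    for i, j in _aligned_columns(template_seq, subunit_seq):
        mapping[template_ids[i]] = subunit_ids[j]
    return {p: mapping[p] for p in template_positions if p in mapping}


def run_design_workflow(config: RunConfig, subunit_path: str | Path,
                        template_path: str | Path, out_dir: str | Path,
                        seed: int | None = None) -> ScreenReport:
    """The 2-to-6 screen: find interfacial sequence differences between a
    candidate subunit and a multimeric template, enumerate all mutation
    combinations toward the template, score, rank, and select.

    Writes ``screen_report.json``, ``ranking.tsv`` and the selected mutant
    assembly as PDB into ``out_dir``.
    """
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    seed = config.seed if seed is None else seed
    template = read_pdb(template_path)
    if len(template.chains) < 2:
        raise ValueError("template is not a multimer")
    subunit = read_pdb(subunit_path)

    ref_chain_id = template.chains[0].chain_id
    symdef = derive_symmetry(template, ref_chain_id)

    # place the subunit in the template reference frame
    template_seq = chain_sequence(template, ref_chain_id)
    sub_chain = subunit.chains[0]
    subunit_seq = chain_sequence(subunit, sub_chain.chain_id)
    from .symmetry import _matched_ca_coords
    ref_ca, sub_ca = _matched_ca_coords(template.get_chain(ref_chain_id),
                                        sub_chain, template_seq, subunit_seq)
    if ref_ca.shape[0] >= 3:
        transform, _ = superpose(sub_ca, ref_ca)
        for _, _, atom in subunit.iter_atoms():
            atom.coords = transform.apply(atom.coords)

    diffs = differing_interface_sites(template, subunit_seq, ref_chain_id)
    template_ids = [r.seq_id for r in template.get_chain(ref_chain_id).sorted_residues()]
    subunit_ids = [r.seq_id for r in sub_chain.sorted_residues()]
    pos_map = _map_positions(template_seq, subunit_seq,
                             [d.position for d in diffs], template_ids, subunit_ids)
    sites = [MutationSite(pos_map[d.position], d.candidate_aa, d.template_aa)
             for d in diffs if d.position in pos_map]
    if not sites:
        raise ValueError("no interfacial sequence differences to screen")

    weights = ScoreWeights(config.pair_cutoff, config.clash_distance,
                           config.clash_weight, config.hbond_weight,
                           config.salt_bridge_weight)
    report = run_screen(subunit, sites, symdef, seed=seed,
                        n_samples=config.n_samples, n_finalists=config.n_finalists,
                        perturb_sigma=config.jitter_sigma,
                        relax_radius=config.relax_radius, weights=weights)

    payload = _report_header(config, {"subunit": subunit_path,
                                      "template": template_path})
    payload["screen"] = report.to_dict()
    (out_dir / "screen_report.json").write_text(
        json.dumps(payload, indent=2, sort_keys=True) + "\n")
    (out_dir / "ranking.tsv").write_text(report.ranking_tsv())
    selected_assembly = report._best_assemblies[report.selected]
    write_pdb(selected_assembly, out_dir / "selected_mutant.pdb")
    return report
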