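"""End-to-end pipeline orchestration from an options dictionary.

The options dictionary (or a YAML-ish key: value input file) drives the whole
run: parse the PDB, cap termini, assign point charges, export the MOL2
charge audit, validate integer residue charges (aborting with a per-residue
report on failure), carve the QM region from the seed (or apply a stored
template), absorb boundary clashes, place link atoms, apply the boundary
charge scheme and write the program input files plus a machine-readable run
manifest.  There is no randomness anywhere in the pipeline: identical
options produce byte-identical outputs.
"""

from __future__ import annotations

import difflib
import json
import logging
import shutil
from dataclasses import dataclass
from pathlib import Path

from . import __version__
from .capping import add_terminal_caps
from .charge_assign import (ChargeTemplateLibrary, IntegerChargeError,
                            WaterModelSpec, assign_charges,
                            load_external_topology, require_integer_charges)
from .fixtures import load_charge_table
from .region import (SeedSpec, absorb_clashes, count_qm_atoms, place_cuts,
                     select_residues)
from .schemes import apply_scheme, get_scheme, report_mm_totals
from .structure import build_bond_graph, parse_pdb, write_mol2_charges
from .templating import (apply_template, extract_template, load_template,
                         save_template)
from .writers import (JobSpec, build_systems, default_filename,
                      make_fsapt_partition, write_fsapt_files, write_input,
                      write_sapt_input)

logger = logging.getLogger(__name__)


class OptionsError(ValueError):
    pass


class PipelineError(RuntimeError):
    def __init__(self, stage: str, original: Exception):
        self.stage = stage
        self.original = original
        super().__init__(f"pipeline stage '{stage}' failed: {original}")


_DEFAULTS = {
    "pdb_file": None,           # required
    "cutoff": 5.0,              # Angstrom
    "seed": "ligand",           # "ligand" or a ligand atom serial
    "charge_scheme": "BRC",
    "charge_source": "bundled",  # bundled | path to RESI topology
    "charge_overrides": None,    # path to a serial->charge table
    "water_model": "tip3p",
    "software": "psi4_format",
    "method": "hf",
    "basis": "sto-3g",
    "counterpoise": False,
    "fsapt": False,
    "sapt_mode": False,
    "template_in": None,
    "template_out": None,
    "ligand_charge": 0,
    "ligand_multiplicity": 1,
    "qm_region_charge": None,
    "qm_region_multiplicity": 1,
    "scf_convergence": 6,
    "ligand_resnames": None,     # explicit ligand residue-name override
    "output_dir": ".",
    "input_filename": None,      # defaults to the PDB stem
    "log_level": "INFO",
    "gap_min": 1,
    "integer_tolerance": 1e-3,
    "extra_keywords": (),
}

_REQUIRED = ("pdb_file",)


def validate_options(options: dict) -> dict:
    """Fill defaults, reject unknown keys (with suggestions), check required."""
    unknown = set(options) - set(_DEFAULTS)
    if unknown:
        hints = []
        for key in sorted(unknown):
            close = difflib.get_close_matches(key, _DEFAULTS, n=1)
            hints.append(f"{key!r}" + (f" (did you mean {close[0]!r}?)"
                                       if close else ""))
        raise OptionsError("unknown option(s): " + ", ".join(hints))
    merged = {**_DEFAULTS, **options}
    missing = [k for k in _REQUIRED if merged[k] is None]
    if missing:
        raise OptionsError("missing required option(s): " + ", ".join(missing))
    if merged["input_filename"] is None:
        merged["input_filename"] = Path(merged["pdb_file"]).stem
    if not isinstance(merged["cutoff"], (int, float)) or merged["cutoff"] <= 0:
        raise OptionsError("cutoff must be a positive number (Angstrom)")
    get_scheme(merged["charge_scheme"])  # raises for unknown schemes
    return merged


def parse_options_file(path) -> dict:
    """Read a key: value options file (YAML subset) into a raw dict."""
    import yaml

    path = Path(path)
    if not path.exists():
        raise OptionsError(f"options file not found: {path}")
    text = path.read_text()
    try:
        data = yaml.safe_load(text)
    except yaml.YAMLError as exc:
        raise OptionsError(f"cannot parse options file {path}: {exc}") from exc
    if data is None:
        raise OptionsError(
            f"options file {path} is empty; required keys: "
            + ", ".join(_REQUIRED)
            + "; known keys: " + ", ".join(sorted(_DEFAULTS)))
    if not isinstance(data, dict):
        raise OptionsError(f"options file {path} must be a key: value mapping")
    return data


@dataclass
class PipelineResult:
    output_dir: Path
    manifest: dict


def run_pipeline(options: dict) -> PipelineResult:
    """Execute all stages; returns the per-cutoff output directory + manifest."""
    opts = validate_options(dict(options))
    outdir = Path(opts["output_dir"]) / \
        f"{opts['input_filename']}_{opts['cutoff']:g}A"
    outdir.mkdir(parents=True, exist_ok=True)
    _setup_logging(opts["log_level"], outdir / "run.log")
    manifest: dict = {"options": {k: (str(v) if isinstance(v, Path) else v)
                                  for k, v in opts.items()},
                      "version": __version__}
    try:
        return _run_stages(opts, outdir, manifest)
    except Exception:
        shutil.rmtree(outdir, ignore_errors=True)  # no partial outputs
        raise


def _run_stages(opts: dict, outdir: Path, manifest: dict) -> PipelineResult:
    def stage(name, fn, *args, **kwargs):
        logger.info("stage: %s", name)
        try:
            return fn(*args, **kwargs)
        except IntegerChargeError:
            raise
        except Exception as exc:
            raise PipelineError(name, exc) from exc

    ligand_resnames = opts["ligand_resnames"]
    if isinstance(ligand_resnames, str):
        ligand_resnames = {ligand_resnames}
    elif ligand_resnames is not None:
        ligand_resnames = set(ligand_resnames)
    model = stage("parse_pdb", parse_pdb, opts["pdb_file"],
                  ligand_resnames=ligand_resnames)
    stage("cap_termini", add_terminal_caps, model)
    model.bonds = stage("bond_graph", build_bond_graph, model)

    if opts["charge_source"] == "bundled":
        library = ChargeTemplateLibrary.bundled()
    else:
        library = stage("load_topology", load_external_topology,
                        opts["charge_source"])
    overrides = None
    if opts["charge_overrides"]:
        overrides = stage("load_charge_overrides", load_charge_table,
                          opts["charge_overrides"])
    water = WaterModelSpec.bundled(opts["water_model"])
    stage("assign_charges", assign_charges, model, library, water, overrides)
    stage("write_mol2", write_mol2_charges, model, outdir / "charges.mol2")
    reports = stage("integer_check", require_integer_charges, model,
                    opts["integer_tolerance"], library)
    manifest["n_residue_reports"] = len(reports)

    seed = (SeedSpec(mode="whole_ligand") if opts["seed"] == "ligand"
            else SeedSpec(mode="atom", atom_serial=int(opts["seed"])))
    if opts["template_in"]:
        template = stage("load_template", load_template, opts["template_in"])
        assignment = stage("apply_template", apply_template, template, model,
                           seed, opts["cutoff"], opts["gap_min"])
    else:
        selected = stage("select_residues", select_residues, model, seed,
                         opts["cutoff"])
        assignment = stage("place_cuts", place_cuts, model, selected)
        assignment = stage("absorb_clashes", absorb_clashes, model,
                           assignment, opts["gap_min"])
    assignment.write_category_map(outdir / "categories.csv")

    pcs = stage("charge_scheme", apply_scheme, assignment, model,
                opts["charge_scheme"])
    pcs.write_audit(outdir / "charge_audit.csv")
    mm_total, n_charges = report_mm_totals(pcs)

    jobspec = JobSpec(software=opts["software"], method=opts["method"],
                      basis=opts["basis"],
                      ligand_charge=opts["ligand_charge"],
                      ligand_multiplicity=opts["ligand_multiplicity"],
                      qm_region_charge=opts["qm_region_charge"],
                      qm_region_multiplicity=opts["qm_region_multiplicity"],
                      counterpoise=opts["counterpoise"],
                      sapt_mode=opts["sapt_mode"], fsapt=opts["fsapt"],
                      scf_convergence=opts["scf_convergence"],
                      extra_keywords=list(opts["extra_keywords"]))
    systems = stage("build_systems", build_systems, assignment, pcs, model,
                    jobspec)
    files = []
    if jobspec.sapt_mode:
        path = outdir / f"sapt.{opts['input_filename']}.psi4.in"
        stage("write_sapt", write_sapt_input, systems["ligand"][0],
              systems["protein"][0], pcs, jobspec, path)
        files.append(path.name)
    else:
        for name in ("ligand", "protein", "complex"):
            system, system_pcs = systems[name]
            path = outdir / default_filename(name, jobspec)
            stage(f"write_{name}", write_input, system, system_pcs, jobspec,
                  path)
            files.append(path.name)
    if jobspec.fsapt:
        partition = stage("fsapt_partition", make_fsapt_partition, assignment,
                          model)
        for path in write_fsapt_files(partition, outdir):
            files.append(path.name)
    if opts["template_out"]:
        template = stage("extract_template", extract_template, assignment,
                         model, opts["cutoff"], seed)
        save_template(template, opts["template_out"])

    n_qm_protein = count_qm_atoms(assignment)
    n_qm_complex = count_qm_atoms(assignment, include_ligand=True, model=model)
    manifest.update({
        "files": files,
        "n_cut_bonds": len(assignment.cut_bonds),
        "qm_atoms_protein": n_qm_protein,
        "qm_atoms_complex": n_qm_complex,
        "ligand_atoms": sum(len(r.atoms) for r in model.ligand_residues),
        "mm_total_charge": mm_total,
        "mm_point_charges": n_charges,
        "qm_region_charge": systems["protein"][0].charge,
    })
    logger.info("QM atoms (protein side, links included): %d", n_qm_protein)
    logger.info("MM total charge: %+.6f e over %d point charges",
                mm_total, n_charges)
    (outdir / "manifest.json").write_text(
        json.dumps(manifest, indent=2, sort_keys=True) + "\n")
    return PipelineResult(output_dir=outdir, manifest=manifest)


def _setup_logging(level: str, logfile: Path) -> None:
    root = logging.getLogger("qmmmprep")
    root.setLevel(getattr(logging, str(level).upper(), logging.INFO))
    have_file = any(isinstance(h, logging.FileHandler)
                    and getattr(h, "baseFilename", None) == str(logfile)
                    for h in root.handlers)
    if not have_file:
        for h in [h for h in root.handlers
                  if isinstance(h, logging.FileHandler)]:
            root.removeHandler(h)
        root.addHandler(logging.FileHandler(logfile, mode="w"))
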