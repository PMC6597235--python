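"""End-to-end orchestration: complexes → profiles → library → screening.

The pipeline has two decoupled halves. Geometry stages (ASA, contacts,
hydrogen bonds) run on structures — here the seeded synthetic pockets,
since docking poses are consumed, not produced. Table stages (key
residues, residue-set comparisons, library drug-likeness, dual-target
consensus, enrichment) run on the packaged reference tables and the
synthetic screens. Every report is a TSV or JSON file and a fixed seed
gives byte-identical output.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import pandas as pd

from dualprofiler import __version__
from dualprofiler.chem_library import compute_descriptors, enumerate_library, lipinski_evaluate
from dualprofiler.fixtures import load_fixtures, load_library_config
from dualprofiler.interactions import ContactParams, find_contacts, find_hbonds, per_residue_counts
from dualprofiler.profile_analysis import (
    build_profile,
    intersect_residue_labels,
    key_residues,
)
from dualprofiler.screening import (
    consensus_topk,
    energy_to_pkd,
    enrichment_factor,
    rank_compounds,
)
from dualprofiler.surface_area import ASAParams, delta_asa
from dualprofiler.structures_io import assign_radii
from dualprofiler.synthetic_data import (
    PocketSpec,
    ScreenSpec,
    make_pocket_complex,
    make_score_table,
)

logger = logging.getLogger(__name__)

__all__ = ["RunConfig", "PipelineError", "run_pipeline"]


class PipelineError(RuntimeError):
    """A stage failed; the message names the stage."""


@dataclass
class RunConfig:
    output_dir: Path = Path("dualprofiler_out")
    seed: int = 0
    k: int = 20
    fraction: float = 0.2
    asa: ASAParams = field(default_factory=ASAParams)
    contacts: ContactParams = field(default_factory=ContactParams)
    library_config: Path | None = None  # None → packaged default
    temperature: float = 298.0

    def __post_init__(self) -> None:
        self.output_dir = Path(self.output_dir)
        if not (0 < self.fraction <= 1):
            raise ValueError("fraction must be in (0, 1]")
        if self.k < 1:
            raise ValueError("k must be >= 1")


def _stage(name):
    def deco(fn):
        def wrapped(*args, **kwargs):
            try:
                return fn(*args, **kwargs)
            except Exception as exc:
                raise PipelineError(f"stage {name!r} failed: {exc}") from exc

        return wrapped

    return deco


@_stage("geometry")
def _geometry_stage(cfg: RunConfig, out: Path) -> dict:
    """Synthetic pockets for two mock targets → binding profiles on disk."""
    specs = {
        "T1": PocketSpec(
            n_residues=6,
            planted_contacts=((1, 3, 3.5), (3, 2, 3.6), (5, 1, 3.45)),
            planted_hbonds=((2, "O", "N", 2.9),),
            planted_burial=(1,),
            seed=cfg.seed,
        ),
        "T2": PocketSpec(
            n_residues=6,
            planted_contacts=((1, 2, 3.4), (3, 4, 3.7)),
            planted_hbonds=((4, "O", "O", 3.0),),
            planted_burial=(3,),
            seed=cfg.seed + 1,
        ),
    }
    summaries = {}
    for target, spec in specs.items():
        pair, ledger = make_pocket_complex(spec, cfg.contacts)
        assign_radii(pair.complex)
        contacts = find_contacts(pair, cfg.contacts)
        hbonds = find_hbonds(pair, cfg.contacts)
        records = per_residue_counts(contacts, hbonds)
        dmap = delta_asa(pair.protein, pair, cfg.asa)
        profile = build_profile(records, dmap, ligand_id="synthetic", target_id=target)
        profile.to_frame().to_csv(out / f"profile_{target}.tsv", sep="\t", index=False)
        report = key_residues(profile)
        summaries[target] = {
            "ledger": ledger,
            "key_residues": {
                "max_delta_asa": [report.max_dasa_residues, round(report.max_dasa_value, 2)],
                "max_contacts": [report.max_contact_residues, report.max_contact_value],
            },
        }
    return summaries


@_stage("profiles")
def _profile_stage(fx, cfg: RunConfig, out: Path) -> dict:
    """Key residues and cross-ligand comparisons from the reference tables."""
    results = {}
    for name, table, target in (("table1", fx.table1, "PI3Kgamma"), ("table3", fx.table3, "mTOR")):
        dasa = dict(zip(table["residue"], table["delta_asa"]))
        from dualprofiler.interactions import InteractionRecord

        records = [
            InteractionRecord(
                residue_key=("A", int(r.residue.split("-")[1]), r.residue.split("-")[0]),
                label=r.residue,
                n_nonbonded=int(r.n_nonbonded),
                n_hbonds=int(getattr(r, "n_hbonds", 0)),
                hbond_lengths=[0.0] * int(getattr(r, "n_hbonds", 0)),
            )
            for r in table.itertuples()
        ]
        profile = build_profile(records, dasa, ligand_id="XL765", target_id=target)
        rep = key_residues(profile)
        results[target] = {
            "max_delta_asa": [rep.max_dasa_residues, rep.max_dasa_value],
            "max_contacts": [rep.max_contact_residues, rep.max_contact_value],
            "total_nonbonded": int(table["n_nonbonded"].sum()),
        }
    common = {
        "PI3Kgamma": intersect_residue_labels(
            fx.membership(fx.table6, "XL765"), fx.membership(fx.table6, "Native")
        ),
        "mTOR": intersect_residue_labels(
            fx.membership(fx.table7, "XL765"), fx.membership(fx.table7, "Native")
        ),
    }
    pd.DataFrame(
        [(t, r) for t, res in common.items() for r in res], columns=["target", "residue"]
    ).to_csv(out / "common_residues.tsv", sep="\t", index=False)
    results["common_with_native"] = common
    return results


@_stage("library")
def _library_stage(cfg: RunConfig, out: Path) -> dict:
    scaffold, r1, r2 = load_library_config(cfg.library_config)
    library = enumerate_library(scaffold, r1, r2)
    rows = []
    for c in library.compounds:
        d = compute_descriptors(c.structure)
        v = lipinski_evaluate(d)
        rows.append(
            {
                "compound": c.compound_number,
                "r1": c.r1_index,
                "r2": c.r2_index,
                "structure": c.structure,
                "mol_weight": round(d.mol_weight, 2),
                "hbd": d.hbd,
                "hba": d.hba,
                "rotatable_bonds": d.rotatable_bonds,
                "logp": round(d.logp, 2),
                "rule_of_five_pass": v.overall_pass,
            }
        )
    frame = pd.DataFrame(rows)
    frame.to_csv(out / "library.tsv", sep="\t", index=False)
    return {"n_compounds": len(library), "numbering": library.numbering}


@_stage("screening")
def _screening_stage(fx, cfg: RunConfig, out: Path) -> dict:
    rankings = {
        t: rank_compounds(fx.s1, t) for t in sorted(fx.s1["target_id"].unique())
    }
    consensus = consensus_topk(rankings, cfg.k)
    (out / "consensus.json").write_text(
        json.dumps({"k": consensus.k, "compounds": consensus.intersection}, indent=2) + "\n"
    )
    # ΔG → pKd for every tabulated binding energy
    t2 = fx.table2.dropna(subset=["binding_energy"]).copy()
    t2["pkd_computed"] = [
        energy_to_pkd(dg, cfg.temperature) for dg in t2["binding_energy"]
    ]
    t2.to_csv(out / "binding_strengths.tsv", sep="\t", index=False)
    return {"consensus": consensus.intersection, "k": consensus.k}


@_stage("enrichment")
def _enrichment_stage(cfg: RunConfig, out: Path) -> dict:
    results = {}
    for i, target in enumerate(("T1", "T2")):
        spec = ScreenSpec(seed=cfg.seed + 100 + i)
        table, labels = make_score_table(spec, target_id=target)
        ranked = table.sort_values(["dock_score", "compound_id"], kind="mergesort")
        classes = labels.set_index("compound_id").loc[ranked["compound_id"], "class"]
        res = enrichment_factor(classes.tolist(), cfg.fraction)
        pd.DataFrame(res.curve, columns=["fraction_screened", "fraction_actives"]).to_csv(
            out / f"enrichment_curve_{target}.tsv", sep="\t", index=False
        )
        results[target] = {
            "ef": round(res.ef, 3),
            "fraction": res.fraction_level,
            "hits_sample": res.hits_sample,
            "n_sample": res.n_sample,
            "hits_database": res.hits_database,
            "n_database": res.n_database,
        }
    return results


def run_pipeline(cfg: RunConfig) -> dict:
    """Run every stage and write the report bundle under ``cfg.output_dir``.

    Returns the summary dict that is also written as ``report.json``.
    """
    out = cfg.output_dir
    out.mkdir(parents=True, exist_ok=True)
    fx = load_fixtures()
    report = {
        "version": __version__,
        "parameters": {
            "seed": cfg.seed,
            "k": cfg.k,
            "fraction": cfg.fraction,
            "probe_radius": cfg.asa.probe_radius,
            "n_sphere_points": cfg.asa.n_sphere_points,
            "contact_window": [cfg.contacts.contact_min, cfg.contacts.contact_max],
            "hbond_max": cfg.contacts.hbond_max,
            "temperature_K": cfg.temperature,
        },
        "geometry": _geometry_stage(cfg, out),
        "profiles": _profile_stage(fx, cfg, out),
        "library": _library_stage(cfg, out),
        "screening": _screening_stage(fx, cfg, out),
        "enrichment": _enrichment_stage(cfg, out),
    }
    (out / "report.json").write_text(json.dumps(report, indent=2, sort_keys=True) + "\n")
    logger.info("pipeline complete: %s", out / "report.json")
    return report
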