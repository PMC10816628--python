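"""End-to-end orchestration: chain score triage, scaffold clustering,
chemical-space projection, and the viability decision cascade into one
reproducible run with per-stage manifests."""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import pandas as pd

from . import chem, hitcalling, io as hio, synthetic_data, triage

log = logging.getLogger("hittriage")


@dataclass
class StageManifest:
    stage: str
    n_in: int
    n_out: int
    n_rejected: int
    detail: dict = field(default_factory=dict)

    def check_flow(self) -> None:
        if self.n_in != self.n_out + self.n_rejected:
            raise AssertionError(
                f"flow conservation violated at {self.stage}: "
                f"{self.n_in} != {self.n_out} + {self.n_rejected}")


def run_pipeline(config: hio.RunConfig) -> dict:
    """Execute the configured stages; returns the run report dict.

    All referenced inputs are checked before any computation; outputs
    are written to ``config.out_dir`` together with the serialized
    config so a run can be reproduced bit-for-bit.
    """
    for label in ("scores", "library", "plates"):
        path = getattr(config, label)
        if path is not None and not Path(path).exists():
            raise FileNotFoundError(f"{label} input not found: {path}")

    out_dir = Path(config.out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    report: dict = {"seed": config.seed, "stages": []}
    manifests: list[StageManifest] = []

    compounds: dict[str, chem.Compound] = {}
    strata: dict[str, str] = {}
    if config.library:
        comp_list, errors = hio.read_smiles_file(config.library)
        compounds = {c.id: c for c in comp_list}
        report["library_errors"] = errors
        for c in comp_list:
            strata[c.id] = c.source.value

    if config.scores:
        records = hio.read_scores_csv(config.scores)
        cfg = config.triage_config()
        survivors = triage.rank_and_cut(records, cfg)
        m = StageManifest("rank_and_cut", len(records), len(survivors),
                          len(records) - len(survivors))
        m.check_flow()
        manifests.append(m)

        kept = survivors
        rejections: list[triage.Rejection] = []
        if compounds:
            descriptors = {
                cid: chem.compute_descriptors(c)
                for cid, c in compounds.items()
            }
            scored_with_structure = [
                r for r in survivors if r.compound_id in compounds]
            kept, rejections = triage.apply_property_filters(
                scored_with_structure, descriptors, cfg, compounds=compounds)
            m = StageManifest(
                "property_filters", len(scored_with_structure), len(kept),
                len(rejections),
                detail={"reasons": [
                    {"compound_id": rj.compound_id, "reason": rj.reason}
                    for rj in rejections]},
            )
            m.check_flow()
            manifests.append(m)
            for rj in rejections:
                log.debug("rejected %s: %s", rj.compound_id, rj.reason)

            shortlist_ids = [r.compound_id for r in kept]
            clusters = triage.cluster_compounds(
                [compounds[cid] for cid in shortlist_ids],
                similarity_threshold=config.similarity_threshold,
                fingerprint_radius=config.fingerprint_radius,
                fingerprint_nbits=config.fingerprint_nbits,
            ) if shortlist_ids else []
            pd.DataFrame([{
                "compound_id": c.compound_id, "cluster_id": c.cluster_id,
                "scaffold_smiles": c.scaffold.smiles,
            } for c in clusters]).to_csv(out_dir / "clusters.tsv", sep="\t",
                                         index=False)

            if len(shortlist_ids) >= 5:
                fps = {cid: chem.morgan_fingerprint(
                    compounds[cid], radius=config.fingerprint_radius,
                    nbits=config.fingerprint_nbits) for cid in shortlist_ids}
                perplexity = min(config.tsne_perplexity,
                                 max(2.0, len(shortlist_ids) - 1.0))
                pts = triage.project_chemical_space(
                    fps, seed=config.seed, strata=strata,
                    perplexity=perplexity)
                pd.DataFrame([{
                    "compound_id": p.compound_id,
                    "x": f"{p.x:.6f}", "y": f"{p.y:.6f}",
                    "stratum": p.stratum,
                } for p in pts]).to_csv(out_dir / "chemical_space.tsv",
                                        sep="\t", index=False)

        shortlist = pd.DataFrame([{
            "compound_id": r.compound_id, "score": f"{r.score:.6f}",
            "ligand_efficiency": (f"{r.ligand_efficiency:.6f}"
                                  if r.ligand_efficiency is not None else ""),
            "status": "kept",
        } for r in kept] + [{
            "compound_id": rj.compound_id, "score": "", "ligand_efficiency": "",
            "status": f"rejected:{rj.reason}",
        } for rj in rejections])
        shortlist.to_csv(out_dir / "shortlist.tsv", sep="\t", index=False)

    if config.plates:
        plate_records = hio.read_plates_csv(config.plates)
        summaries = hitcalling.normalize_viability(plate_records)
        decisions = hitcalling.run_cascade(
            summaries.values(), config.cascade_thresholds())
        counts = hitcalling.cascade_counts(decisions)
        m = StageManifest(
            "cascade", len(decisions),
            counts["BEST"],
            len(decisions) - counts["BEST"],
            detail={"category_counts": counts},
        )
        m.check_flow()
        manifests.append(m)
        hitcalling.decisions_frame(decisions).to_csv(
            out_dir / "decisions.tsv", sep="\t", index=False)
        best = sorted(d.compound_id for d in decisions
                      if d.category is hitcalling.Category.BEST)
        report["best_compounds"] = best
        report["cascade_counts"] = counts

    report["stages"] = [{
        "stage": m.stage, "in": m.n_in, "out": m.n_out,
        "rejected": m.n_rejected, **({"detail": m.detail} if m.detail else {}),
    } for m in manifests]
    config.to_json(out_dir / "run_config.json")
    (out_dir / "report.json").write_text(
        json.dumps(report, indent=1, sort_keys=True) + "\n")
    return report


def run_fixture_cascade(thresholds=None) -> dict:
    """Run the decision cascade on the packaged campaign fixture."""
    fixture = synthetic_data.build_paper_fixture()
    decisions = hitcalling.run_cascade(fixture.summaries, thresholds)
    counts = hitcalling.cascade_counts(decisions)
    best = sorted(
        (d.compound_id for d in decisions
         if d.category is hitcalling.Category.BEST),
        key=synthetic_data._natural_key)
    cytotoxic = sorted(
        (d.compound_id for d in decisions
         if d.category is hitcalling.Category.CYTOTOXIC_10uM),
        key=synthetic_data._natural_key)
    return {
        "n_acquired": len(fixture.acquisition),
        "n_excluded": len(fixture.exclusions),
        "n_evaluated": len(fixture.evaluated_ids),
        "counts": counts,
        "best_ids": best,
        "cytotoxic_10um_ids": cytotoxic,
        "decisions": decisions,
        "fixture": fixture,
    }
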