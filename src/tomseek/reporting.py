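"""Run-level reporting: EM class-average accounting, config, pipeline.

``class_fractions`` does the pore-count arithmetic for negative-stain EM
class averages (how many class averages show one, two or three translocase
channels). ``pipeline_run`` wires every stage together on synthetic input:
simulate a proteome -> motif scan -> profile-HMM search -> TMD/anchor calls
-> LFQ enrichment -> triage -> similarity network -> gain/loss profiling,
writing per-stage TSVs, a JSON summary and the fully resolved config.
"""

from __future__ import annotations

import copy
import json
import math
from dataclasses import dataclass
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
import yaml

from . import (
    candidate_triage,
    lfq_enrichment,
    motif_scan,
    phyloprofile,
    profile_hmm,
    sequence_io,
    similarity_network,
    synthetic_data,
    tmd_predict,
)


@dataclass(frozen=True)
class ClassAverageStats:
    label: str
    pore_count: int
    n_particles: int
    resolution_A: float | None = None

    def __post_init__(self):
        if self.pore_count not in (1, 2, 3):
            raise ValueError("pore_count must be 1, 2 or 3")
        if self.n_particles < 0:
            raise ValueError("n_particles must be non-negative")


def _round_half_away(x: float) -> int:
    return int(math.floor(x + 0.5)) if x >= 0 else -int(math.floor(-x + 0.5))


def class_fractions(
    stats: Sequence[ClassAverageStats], total: int | None = None
) -> dict[str, dict[str, float | int]]:
    """Per-class particle fraction and nearest-integer percent.

    ``total`` defaults to the sum of class particle counts; pass a larger
    total to express classes as a share of a bigger particle set. Raw
    fractions are always reported alongside the rounded percents because
    rounding conventions differ between publications.
    """
    if total is None:
        total = sum(s.n_particles for s in stats)
    if total <= 0:
        raise ValueError("total must be positive")
    out = {}
    for s in stats:
        frac = s.n_particles / total
        out[s.label] = {
            "n": s.n_particles,
            "fraction": frac,
            "percent": _round_half_away(100.0 * frac),
        }
    return out


# --------------------------------------------------------------------------
# run configuration

DEFAULT_CONFIG: dict = {
    "seed": 17,
    "motif": {"pattern": "PxGxxHxH", "cterm_window": 40},
    "hmm": {
        "occupancy_threshold": 0.5,
        "pseudocount_weight": 1.0,
        "n_decoys": 100,
        "decoy_length": 120,
    },
    "tmd": {"cutoff": 0.7, "min_len": 15, "merge_gap": 3, "window": 19,
            "cterm_window": 35, "nterm_window": 35},
    "lfq": {"fc_threshold": 1.0, "min_present_test": 2,
            "max_present_control_for_absence": 0, "fc_scale": "linear"},
    "network": {"p_cutoff": 0.1, "n_iter": 2000, "show_top": 0.2},
    "proteome": {"n_decoys": 60, "decoy_length": 120,
                 "n_barrels": 7, "mutation_rate": 0.05},
    "treeprofile": {"n_leaves": 12, "p_loss": 0.2},
}


class ConfigError(ValueError):
    pass


def resolve_config(overrides: Mapping | None = None) -> dict:
    """Merge user overrides into the defaults; unknown keys are rejected."""
    config = copy.deepcopy(DEFAULT_CONFIG)

    def merge(base: dict, over: Mapping, path: str) -> None:
        for key, value in over.items():
            if key not in base:
                raise ConfigError(f"unknown config key {path + key!r}")
            if isinstance(base[key], dict):
                if not isinstance(value, Mapping):
                    raise ConfigError(f"{path + key!r} expects a mapping")
                merge(base[key], value, path + key + ".")
            else:
                base[key] = value

    if overrides:
        merge(config, overrides, "")
    return config


def load_config(path: str | Path) -> dict:
    with open(path) as fh:
        data = yaml.safe_load(fh) or {}
    return resolve_config(data)


# --------------------------------------------------------------------------
# end-to-end pipeline on synthetic input


def pipeline_run(config: Mapping | None, outdir: str | Path) -> dict:
    """Execute every stage on a simulated dataset; returns the summary."""
    cfg = resolve_config(config if config is not None else {})
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    seed = int(cfg["seed"])
    summary: dict = {"seed": seed, "stages": {}}

    def stage(name):
        def wrap(fn):
            try:
                fn()
            except Exception as exc:
                raise RuntimeError(f"pipeline stage {name!r} failed: {exc}") from exc
        return wrap

    # --- simulate proteome -------------------------------------------------
    pcfg = cfg["proteome"]
    families = [
        synthetic_data.FamilySpec(
            f"TOM40P{i + 1}",
            "barrel_ser" if i == 2 else "barrel",  # third paralogue broken
            1,
            pcfg["mutation_rate"],
        )
        for i in range(pcfg["n_barrels"])
    ] + [
        synthetic_data.FamilySpec("TOM40FAM", "barrel", 8, pcfg["mutation_rate"]),
        synthetic_data.FamilySpec("TOM36", "hsp20_tpr_tmd", 1, 0.02),
        synthetic_data.FamilySpec("TOM46", "hsp20_tpr_tmd", 1, 0.05),
        synthetic_data.FamilySpec("TOM22L", "tom22_like", 1, 0.02),
    ]
    prot_spec = synthetic_data.ProteomeSpec(
        families=tuple(families),
        n_decoys=pcfg["n_decoys"],
        decoy_length=pcfg["decoy_length"],
    )

    state: dict = {}

    @stage("simulate_proteome")
    def _():
        records, truth = synthetic_data.gen_proteome(prot_spec, seed)
        sequence_io.write_fasta(records, outdir / "proteome.fasta")
        truth.to_csv(outdir / "proteome_truth.tsv", sep="\t", index=False)
        state["records"], state["truth"] = records, truth

    # --- motif scan --------------------------------------------------------
    @stage("motif_scan")
    def _():
        mcfg = cfg["motif"]
        pattern = motif_scan.compile_pattern(mcfg["pattern"])
        rows = []
        for rec in state["records"]:
            for h in motif_scan.scan(rec, pattern, mcfg["cterm_window"]):
                rows.append(motif_scan.hits_table([h])[0])
        pd.DataFrame(
            rows, columns=["record_id", "start", "matched", "in_cterm_window"]
        ).to_csv(outdir / "motif_hits.tsv", sep="\t", index=False)
        barrels = [
            r for r in state["records"]
            if state["truth"].set_index("record_id").loc[r.id, "template"]
            in ("barrel", "barrel_ser")
            and r.id.startswith("TOM40P")
        ]
        pos, neg = motif_scan.classify_candidates(
            barrels, pattern, mcfg["cterm_window"]
        )
        summary["stages"]["motif_scan"] = {
            "paralogues_motif_positive": len(pos),
            "paralogues_motif_negative": len(neg),
        }

    # --- profile-HMM search ------------------------------------------------
    @stage("hmm_search")
    def _():
        hcfg = cfg["hmm"]
        family = [r for r in state["records"] if r.id.startswith("TOM40FAM")]
        aln = sequence_io.alignment_from_records(family)
        hmm = profile_hmm.build_hmm(
            aln, hcfg["occupancy_threshold"], hcfg["pseudocount_weight"]
        )
        calib = profile_hmm.calibrate_evalue(
            hmm, hcfg["n_decoys"], hcfg["decoy_length"], seed=seed
        )
        targets = [r for r in state["records"] if not r.id.startswith("TOM40FAM")]
        hits = profile_hmm.search_proteome(hmm, targets, calib, compute_spans=False)
        pd.DataFrame(
            [
                {"record_id": h.record_id, "bit_score": round(h.bit_score, 4),
                 "e_value": f"{h.e_value:.3e}",
                 "span": f"{h.span[0]}-{h.span[1]}"}
                for h in hits
            ]
        ).to_csv(outdir / "hmm_hits.tsv", sep="\t", index=False)
        summary["stages"]["hmm_search"] = {
            "top_hit": hits[0].record_id,
            "top_hit_is_planted_barrel": bool(
                hits[0].record_id.startswith(("TOM40P", "TOM40FAM"))
            ),
        }
        state["hmm_family"] = family

    # --- TMD / anchor calls ------------------------------------------------
    @stage("tmd")
    def _():
        tcfg = cfg["tmd"]
        calls = {}
        rows = []
        for rec in state["records"]:
            spans = tmd_predict.predict_tmds(
                rec.sequence, tcfg["cutoff"], tcfg["min_len"],
                tcfg["merge_gap"], tcfg["window"],
            )
            call = tmd_predict.classify_anchor(
                rec, spans, tcfg["cterm_window"], tcfg["nterm_window"]
            )
            calls[rec.id] = call
            rows.append(
                {
                    "record_id": rec.id,
                    "n_spans": len(call.spans),
                    "category": call.category,
                    "spans": ";".join(f"{s.start}-{s.end}" for s in call.spans),
                }
            )
        pd.DataFrame(rows).to_csv(outdir / "tmd_calls.tsv", sep="\t", index=False)
        state["anchor_calls"] = calls
        summary["stages"]["tmd"] = {
            "tail_anchored": sorted(
                k for k, v in calls.items() if v.category == "tail_anchored"
            )
        }

    # --- LFQ enrichment (two conditions) ------------------------------------
    @stage("lfq")
    def _():
        lcfg = cfg["lfq"]
        member_ids = [
            r.id for r in state["records"]
            if r.id.startswith(("TOM40P", "TOM36", "TOM46", "TOM22L"))
        ]
        sets = {}
        for cond, cond_seed in (("crosslink", seed), ("native", seed + 1)):
            spec = synthetic_data.LfqSpec(n_proteins=120, n_members=0)
            table, _ = synthetic_data.gen_lfq(spec, cond_seed)
            frame = table.frame.copy()
            rng = np.random.default_rng(cond_seed + 7)
            extra = []
            members = member_ids if cond == "crosslink" else member_ids[:-2]
            for acc in members:
                mu = rng.uniform(22, 28)
                row = {"accession": acc, "name": acc}
                row.update(
                    {c: mu + 3.0 + rng.normal(0, 0.4) for c in lfq_enrichment.TEST_COLS}
                )
                row.update({c: np.nan for c in lfq_enrichment.CTRL_COLS})
                extra.append(row)
            frame = pd.concat([frame, pd.DataFrame(extra)], ignore_index=True)
            table = lfq_enrichment.LfqTable(frame)
            results = lfq_enrichment.compute_enrichment(
                table, lcfg["fc_threshold"], lcfg["min_present_test"],
                lcfg["max_present_control_for_absence"], lcfg["fc_scale"],
            )
            lfq_enrichment.results_frame(results).to_csv(
                outdir / f"enrichment_{cond}.tsv", sep="\t", index=False
            )
            sets[cond] = lfq_enrichment.enriched_set(results)
        state["enriched"] = sets
        summary["stages"]["lfq"] = {c: len(s) for c, s in sets.items()}

    # --- triage --------------------------------------------------------------
    @stage("triage")
    def _():
        membrane = set(
            state["truth"].loc[state["truth"]["membrane"], "record_id"]
        )
        candidates = candidate_triage.triage(
            state["enriched"]["crosslink"],
            state["enriched"]["native"],
            membrane,
            state["anchor_calls"],
        )
        pd.DataFrame([c.__dict__ for c in candidates]).to_csv(
            outdir / "candidates.tsv", sep="\t", index=False
        )
        summary["stages"]["triage"] = {
            "tier1": sorted(c.accession for c in candidates if c.tier == 1),
            "tier2": sorted(c.accession for c in candidates if c.tier == 2),
        }

    # --- similarity network ---------------------------------------------------
    @stage("network")
    def _():
        ncfg = cfg["network"]
        fam_a = [r for r in state["records"] if r.id.startswith("TOM40FAM")][:8]
        fam_b = [
            r for r in state["records"] if r.id.startswith(("TOM36", "TOM46"))
        ]
        decoys = [r for r in state["records"] if r.id.startswith("DEC")][:6]
        nodes = fam_a + fam_b + decoys
        edges = similarity_network.pairwise_similarity(
            nodes, p_cutoff=ncfg["p_cutoff"]
        )
        lay = similarity_network.layout(
            edges, [r.id for r in nodes], ncfg["n_iter"], seed
        )
        comps = similarity_network.components(edges, [r.id for r in nodes])
        pd.DataFrame(
            [
                {"id1": e.pair[0], "id2": e.pair[1],
                 "score": e.raw_score, "p_value": f"{e.p_value:.3e}",
                 "attraction": round(e.attraction, 3)}
                for e in edges
            ]
        ).to_csv(outdir / "network_edges.tsv", sep="\t", index=False)
        comp_of = {}
        for idx, comp in enumerate(comps):
            for node in comp:
                comp_of[node] = idx
        pd.DataFrame(
            {
                "id": lay.ids,
                "x": np.round(lay.coordinates[:, 0], 6),
                "y": np.round(lay.coordinates[:, 1], 6),
                "component": [comp_of[i] for i in lay.ids],
            }
        ).to_csv(outdir / "network_layout.tsv", sep="\t", index=False)
        summary["stages"]["network"] = {
            "n_edges": len(edges),
            "n_components": len(comps),
        }

    # --- phyloprofile ---------------------------------------------------------
    @stage("phyloprofile")
    def _():
        tcfg = cfg["treeprofile"]
        spec = synthetic_data.TreeProfileSpec(
            n_leaves=tcfg["n_leaves"], p_loss=tcfg["p_loss"]
        )
        tree, profile, truth = synthetic_data.gen_tree_profile(spec, seed)
        entries, table = phyloprofile.profile_report(tree, profile)
        (outdir / "species_tree.nwk").write_text(phyloprofile.write_newick(tree) + "\n")
        profile.to_tsv(outdir / "phyloprofile.tsv")
        table.to_csv(outdir / "gainloss_report.tsv", sep="\t", index=False)
        summary["stages"]["phyloprofile"] = {
            "components": {
                c: {"losses": e.n_losses, "recovered_gain": truth.gain_clades[c]
                    == e.gain_clade}
                for c, e in entries.items()
            }
        }

    with open(outdir / "summary.json", "w") as fh:
        json.dump(summary, fh, indent=2, sort_keys=True)
    with open(outdir / "resolved_config.yaml", "w") as fh:
        yaml.safe_dump(cfg, fh, sort_keys=True)
    return summary
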