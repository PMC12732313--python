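"""End-to-end orchestration of the synthetic FKP analysis pipeline.

Stage order: simulate -> classify -> ssn -> phylo -> conserve, with
kinetics and melt as parallel tracks.  All randomness derives from one
top-level seed; per-stage seeds are spawned deterministically.  A run
manifest (JSON) records the config, seed, per-stage output checksums and
wall time, and is written even when a stage fails.  Output files are
checksum-gated: rerunning an identical configuration rewrites nothing.
"""

from __future__ import annotations

import copy
import difflib
import hashlib
import json
import logging
import time
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import __version__
from . import conservation, domains, meltcurve, phylo, ssn
from .kinetics import fit_mm
from .simulate import (
    CensusConfig,
    KineticTruth,
    MeltTruth,
    SimConfig,
    fasta_string,
    gen_census_alignment,
    gen_domain_families,
    gen_fusion_tree,
    gen_hit_table,
    gen_melt_curve,
    gen_rate_data,
    truth_manifest_string,
)

log = logging.getLogger(__name__)

__all__ = ["DEFAULT_CONFIG", "ConfigError", "validate_config", "run_pipeline"]

STAGES = ("simulate", "classify", "ssn", "phylo", "conserve", "kinetics", "melt")

DEFAULT_CONFIG: dict = {
    "seed": 0,
    "outdir": "fkpkit_out",
    "stages": {name: True for name in STAGES},
    "simulate": {
        "n_fuk": 5,
        "n_gfpp": 5,
        "n_fkp": 5,
        "domain_len_fuk": 400,
        "domain_len_gfpp": 450,
        "linker_len": 20,
        "substitution_rate": 0.15,
        "score_noise_sd": 0.0,
        "tree_n_tips": 16,
        "fusion_clade_size": 5,
        "loss_count": 0,
    },
    "classify": {
        "min_fuk_len": 333,
        "min_gfpp_len": 406,
        "min_fkp_len": 739,
        "max_len": 1745,
    },
    "ssn": {"threshold": 40.0, "min_cluster_size": 2},
    "conserve": {"n_rows": 186, "n_gap_prefixed": 15, "boundary": 88},
    "kinetics": {
        "KM_uM": 77.0,
        "kcat_per_s": 0.90,
        "E0_uM": 0.277,
        "noise_cv": 0.05,
        "n_reps": 3,
    },
    "melt": {
        "tm1_C": 43.8,
        "tm2_C": 52.5,
        "noise_sd": 2.0,
        "n_reps": 3,
    },
}


class ConfigError(ValueError):
    pass


def _merge(defaults: dict, user: dict, path: str = "") -> dict:
    out = copy.deepcopy(defaults)
    for key, val in user.items():
        here = f"{path}.{key}" if path else key
        if key not in defaults:
            hint = difflib.get_close_matches(key, defaults.keys(), n=1)
            extra = f" (did you mean {hint[0]!r}?)" if hint else ""
            raise ConfigError(f"unknown config key {here!r}{extra}")
        if isinstance(defaults[key], dict):
            if not isinstance(val, dict):
                raise ConfigError(f"{here!r} must be a mapping")
            out[key] = _merge(defaults[key], val, here)
        else:
            if isinstance(defaults[key], bool) and not isinstance(val, bool):
                raise ConfigError(f"{here!r} must be a boolean")
            if isinstance(defaults[key], (int, float)) and not isinstance(
                val, (int, float)
            ):
                raise ConfigError(f"{here!r} must be numeric, got {type(val).__name__}")
            out[key] = val
    return out


def validate_config(path=None, overrides: dict | None = None) -> dict:
    """Load and normalize a YAML pipeline config.

    Missing keys take defaults; unknown keys are rejected with a
    suggestion.  ``overrides`` (e.g. from CLI flags) are merged last.
    """
    user: dict = {}
    if path is not None:
        with open(path) as fh:
            loaded = yaml.safe_load(fh)
        if loaded is not None:
            if not isinstance(loaded, dict):
                raise ConfigError("config must be a YAML mapping")
            user = loaded
    cfg = _merge(DEFAULT_CONFIG, user)
    if overrides:
        cfg = _merge(cfg, overrides)
    return cfg


def _stage_seed(seed: int, stage: str) -> int:
    """Deterministic per-stage seed below 2**31."""
    digest = hashlib.sha256(f"{seed}:{stage}".encode()).digest()
    return int.from_bytes(digest[:4], "big") % (2**31)


def _sha256(path: Path) -> str:
    return hashlib.sha256(path.read_bytes()).hexdigest()


def _write_gated(path: Path, content: str) -> bool:
    """Write only if content differs; returns True if the file was touched."""
    data = content.encode()
    if path.exists() and hashlib.sha256(path.read_bytes()).hexdigest() == hashlib.sha256(data).hexdigest():
        return False
    path.write_bytes(data)
    return True


def _write_df(path: Path, df: pd.DataFrame, sep: str) -> bool:
    return _write_gated(path, df.to_csv(sep=sep, index=False))


def run_pipeline(config: dict) -> dict:
    """Execute the enabled stages and return the run manifest."""
    outdir = Path(config["outdir"])
    outdir.mkdir(parents=True, exist_ok=True)
    seed = int(config["seed"])
    manifest: dict = {
        "tool": "fkpkit",
        "version": __version__,
        "seed": seed,
        "config_hash": hashlib.sha256(
            json.dumps(config, sort_keys=True).encode()
        ).hexdigest(),
        "stages": {},
        "failure": None,
    }
    state: dict = {}
    t0 = time.monotonic()
    enabled = config["stages"]
    if enabled["classify"] and not enabled["simulate"]:
        raise ConfigError("classify requires the simulate stage (no external input configured)")

    def record(stage: str, outputs: dict[str, Path], extra: dict | None = None):
        manifest["stages"][stage] = {
            "outputs": {name: _sha256(p) for name, p in outputs.items()},
            **(extra or {}),
        }

    try:
        if enabled["simulate"]:
            s = config["simulate"]
            sim = SimConfig(seed=_stage_seed(seed, "simulate"), **s)
            proteins, truth = gen_domain_families(sim)
            hits = gen_hit_table(
                proteins, truth, sim.score_noise_sd, seed=_stage_seed(seed, "hits")
            )
            tree, tree_truth = gen_fusion_tree(
                sim.tree_n_tips, sim.fusion_clade_size, sim.loss_count,
                seed=_stage_seed(seed, "tree"),
            )
            fasta = outdir / "proteins.fasta"
            _write_gated(fasta, fasta_string(proteins))
            hits_path = outdir / "hits.tsv"
            _write_df(hits_path, hits, "\t")
            tree_path = outdir / "fusion_tree.nwk"
            _write_gated(tree_path, phylo.write_newick(tree))
            manifest_path = outdir / "truth.yaml"
            _write_gated(
                manifest_path,
                truth_manifest_string(seed, families=truth, tree=tree_truth),
            )
            state.update(
                proteins=proteins, truth=truth, hits=hits, tree=tree,
                tree_truth=tree_truth,
            )
            record("simulate", {
                "proteins.fasta": fasta, "hits.tsv": hits_path,
                "fusion_tree.nwk": tree_path, "truth.yaml": manifest_path,
            })

        if enabled["classify"]:
            c = config["classify"]
            thresholds = domains.LengthThresholds(
                min_fuk=c["min_fuk_len"], min_gfpp=c["min_gfpp_len"],
                min_fkp=c["min_fkp_len"], max_len=c["max_len"],
            )
            ranked = domains.rank_models(state["hits"])
            lengths = {pid: len(seq) for pid, seq in state["proteins"].items()}
            calls = domains.classify_architecture(ranked, lengths, thresholds)
            truth = state["truth"]
            predicted = calls.apply(
                lambda r: "FKP" if r["in_fkp_set"]
                else "FUK" if r["in_fuk_set"]
                else "GFPP" if r["in_gfpp_set"] else "none",
                axis=1,
            )
            accuracy = float(
                np.mean([
                    p == truth.family[q]
                    for q, p in zip(calls["query_id"], predicted)
                ])
            )
            calls_path = outdir / "calls.tsv"
            _write_df(calls_path, calls, "\t")
            state["calls"] = calls
            record("classify", {"calls.tsv": calls_path},
                   {"accuracy_vs_truth": accuracy})

        if enabled["ssn"]:
            cfg = config["ssn"]
            mat = ssn.identity_matrix(state["proteins"])
            graph = ssn.build_ssn(mat, cfg["threshold"])
            clusters = ssn.ssn_clusters(graph, cfg["min_cluster_size"])
            _, purity, overall = ssn.cluster_clade_congruence(
                clusters, state["truth"].family
            )
            edges = pd.DataFrame(
                [(u, v, d["identity"]) for u, v, d in graph.edges(data=True)],
                columns=["source", "target", "identity"],
            )
            nodes = pd.DataFrame(
                [(n, clusters[n], state["truth"].family[n]) for n in graph.nodes],
                columns=["id", "cluster", "family"],
            )
            e_path, n_path = outdir / "ssn_edges.tsv", outdir / "ssn_nodes.tsv"
            _write_df(e_path, edges, "\t")
            _write_df(n_path, nodes, "\t")
            state["clusters"] = clusters
            record("ssn", {"ssn_edges.tsv": e_path, "ssn_nodes.tsv": n_path},
                   {"n_clusters": int(max(clusters.values(), default=0)),
                    "family_purity": overall})

        if enabled["phylo"]:
            tree, tree_truth = state["tree"], state["tree_truth"]
            character = dict(tree_truth.tip_state)
            events = phylo.fitch_fusion_events(tree, character)
            unrooted = tree.clone(depth=1)
            unrooted.is_rooted = False
            roots = phylo.monophyly_roots(
                unrooted, [t for t, s in character.items() if s == 1]
            ) if any(character.values()) else set()
            mid = phylo.midpoint_root(tree)
            mid_path = outdir / "midpoint_rooted.nwk"
            _write_gated(mid_path, phylo.write_newick(mid))
            record("phylo", {"midpoint_rooted.nwk": mid_path},
                   {"fitch_events": events, "n_monophyly_roots": len(roots)})

        if enabled["conserve"]:
            cfg = config["conserve"]
            census = CensusConfig(
                n_rows=cfg["n_rows"], n_gap_prefixed=cfg["n_gap_prefixed"]
            )
            aln, clades, ref_id = gen_census_alignment(
                census, seed=_stage_seed(seed, "conserve")
            )
            ref_map = conservation.map_ref_positions(
                aln, ref_id, list(census.gfpp_positions + census.kinase_positions)
            )
            retained = conservation.apply_exclusion(aln, ref_id, cfg["boundary"])
            retained_census = [r for r in retained if r != ref_id]
            table = conservation.conservation_fraction(aln, ref_map, retained_census)
            strata = conservation.stratify_missing(
                aln, ref_map, retained_census, clades,
                position_subset=[int(t[1:]) for t in census.gfpp_positions],
            )
            cons_path = outdir / "conservation.tsv"
            _write_df(cons_path, table, "\t")
            record("conserve", {"conservation.tsv": cons_path},
                   {"n_retained": len(retained_census),
                    "missing_by_clade": {k: float(v) for k, v in strata.items()}})

        if enabled["kinetics"]:
            cfg = config["kinetics"]
            truth = KineticTruth(
                KM=cfg["KM_uM"], kcat=cfg["kcat_per_s"], E0=cfg["E0_uM"],
                noise_cv=cfg["noise_cv"],
            )
            concs = truth.KM * np.array([0.25, 0.5, 1, 2, 3, 5, 8, 10])
            data = gen_rate_data(
                truth, concs, n_reps=cfg["n_reps"], model="mm",
                seed=_stage_seed(seed, "kinetics"),
            )
            fit = fit_mm(data, truth.E0)
            eff, eff_sd = fit.efficiency
            rates_path = outdir / "rates.csv"
            _write_df(rates_path, data, ",")
            fit_path = outdir / "kinetic_fit.tsv"
            _write_df(fit_path, pd.DataFrame([{
                "KM_uM": fit.KM, "KM_sd": fit.KM_sd,
                "kcat_per_s": fit.kcat, "kcat_sd": fit.kcat_sd,
                "eff_per_M_s": eff, "eff_sd": eff_sd,
            }]), "\t")
            record("kinetics", {"rates.csv": rates_path, "kinetic_fit.tsv": fit_path},
                   {"KM_uM": fit.KM, "kcat_per_s": fit.kcat})

        if enabled["melt"]:
            cfg = config["melt"]
            truth = MeltTruth(
                transitions=((cfg["tm1_C"], 1.0, 500.0), (cfg["tm2_C"], 1.0, 700.0)),
                noise_sd=cfg["noise_sd"],
            )
            results = []
            frames = []
            for rep in range(1, cfg["n_reps"] + 1):
                curve = gen_melt_curve(
                    truth, seed=_stage_seed(seed, f"melt{rep}"), replicate=rep
                )
                frames.append(curve)
                results.append(meltcurve.analyze_curve(curve))
            melt_path = outdir / "melt_curves.csv"
            _write_df(melt_path, pd.concat(frames, ignore_index=True), ",")
            summary = meltcurve.summarize_replicates(results)
            sum_path = outdir / "melt_summary.tsv"
            _write_df(sum_path, summary, "\t")
            record("melt", {"melt_curves.csv": melt_path, "melt_summary.tsv": sum_path},
                   {"tms": summary.to_dict("records")})
    except Exception as exc:
        stage = next((s for s in STAGES if enabled.get(s) and s not in manifest["stages"]), "?")
        manifest["failure"] = {"stage": stage, "error": str(exc)}
        manifest["wall_time_s"] = time.monotonic() - t0
        (outdir / "manifest.json").write_text(json.dumps(manifest, indent=2))
        raise
    manifest["wall_time_s"] = time.monotonic() - t0
    (outdir / "manifest.json").write_text(json.dumps(manifest, indent=2))
    return manifest
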