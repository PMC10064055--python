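"""End-to-end analysis pipeline.

Runs the full chain — preprocessing, OTU partition, richness tests,
community ordination and permutation tests, phylogenetic signal, network
metrics with null-model standardization, and robustness — from a single
config, either on files (two OTU tables + a host tree) or on the synthetic
generators.  Every stage draws its randomness from a named substream of the
master seed, so runs are reproducible and adding a stage never perturbs the
results of earlier ones.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import zlib
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import yaml

from . import community as comm
from . import network as net
from . import nulls, otu_io, robustness as rob
from .phylo import blomberg_k, cophenetic_distances, pagel_lambda, read_newick
from .simulate import CommunitySimParams, simulate_paired_communities, simulate_tree

__all__ = ["PipelineConfig", "run_pipeline", "ALL_STAGES"]

ALL_STAGES = ("preprocess", "community", "signal", "network", "robustness")


@dataclass
class PipelineConfig:
    """Inputs, preprocessing rules, test sizes and the master seed.

    Either all three input paths (``epi_table``, ``endo_table``, ``tree``)
    must be given, or a ``synthetic`` block; with a synthetic block the
    generator seed is derived from the master seed.
    """

    epi_table: str | None = None
    endo_table: str | None = None
    tree: str | None = None
    synthetic: CommunitySimParams | None = None
    min_reads: int = 10
    rarefaction_depth: int | str | None = "min"
    n_null: int = 1000
    n_perm_anosim: int = 9999
    n_perm_mantel: int = 999
    n_perm_k: int = 999
    n_rep_extinction: int = 100
    nmds_starts: int = 20
    modularity_restarts: int = 20
    modularity_restarts_null: int = 5
    seed: int = 0
    stages: tuple[str, ...] = ALL_STAGES
    output_dir: str | None = None

    def __post_init__(self) -> None:
        has_paths = all(p is not None for p in (self.epi_table, self.endo_table, self.tree))
        if not has_paths and self.synthetic is None:
            raise ValueError(
                "config needs either epi_table/endo_table/tree paths "
                "or a synthetic block"
            )
        unknown = set(self.stages) - set(ALL_STAGES)
        if unknown:
            raise ValueError(f"unknown stage(s): {sorted(unknown)}")
        if isinstance(self.synthetic, dict):
            self.synthetic = CommunitySimParams(**self.synthetic)

    @classmethod
    def from_yaml(cls, path) -> "PipelineConfig":
        with open(path) as fh:
            data = yaml.safe_load(fh)
        if "stages" in data:
            data["stages"] = tuple(data["stages"])
        return cls(**data)

    def content_hash(self) -> str:
        d = dataclasses.asdict(self)
        d.pop("output_dir", None)  # where results land is not part of the analysis
        return hashlib.sha256(
            json.dumps(d, sort_keys=True, default=str).encode()
        ).hexdigest()[:16]


def stage_seed(master_seed: int, stage: str) -> int:
    """Stable per-stage substream seed (crc32 of the stage name, xor master)."""
    return (zlib.crc32(stage.encode()) ^ master_seed) % (2**31)


def _load_inputs(cfg: PipelineConfig):
    if cfg.synthetic is not None:
        params = dataclasses.replace(
            cfg.synthetic, seed=stage_seed(cfg.seed, "simulate-communities")
        )
        tree = simulate_tree(params.n_hosts, stage_seed(cfg.seed, "simulate-tree"))
        epi, endo = simulate_paired_communities(tree, params)
        return epi, endo, tree
    epi = otu_io.read_otu_table(cfg.epi_table)
    endo = otu_io.read_otu_table(cfg.endo_table)
    tree = read_newick(cfg.tree)
    return epi, endo, tree


def _preprocess(cfg: PipelineConfig, epi, endo):
    epi = otu_io.filter_low_count(epi, cfg.min_reads)
    endo = otu_io.filter_low_count(endo, cfg.min_reads)
    depth = cfg.rarefaction_depth
    if depth == "min":
        depth = int(
            min(epi.sample_totals().min(), endo.sample_totals().min())
        )
    if depth is not None:
        seed = stage_seed(cfg.seed, "rarefy")
        epi = otu_io.rarefy(epi, int(depth), seed)
        endo = otu_io.rarefy(endo, int(depth), seed + 1)
    return epi, endo, depth


def _combined_distance(epi, endo) -> comm.DistanceMatrix:
    """Bray-Curtis over both compartments' samples on the union OTU set."""
    union = sorted(set(epi.otu_ids) | set(endo.otu_ids))
    pos = {o: j for j, o in enumerate(union)}
    rows = []
    ids = []
    for prefix, table in (("epi", epi), ("endo", endo)):
        mat = np.zeros((table.n_samples, len(union)))
        for j, o in enumerate(table.otu_ids):
            mat[:, pos[o]] = table.counts[:, j]
        rows.append(mat)
        ids.extend(f"{prefix}:{s}" for s in table.sample_ids)
    stacked = np.vstack(rows)
    hel = np.sqrt(stacked / stacked.sum(axis=1, keepdims=True))
    return comm.bray_curtis(hel, ids)


def _permutation_result_dict(res: comm.PermutationTestResult) -> dict:
    return {
        "statistic": res.statistic,
        "p_value": res.p_value,
        "n_permutations": res.n_permutations,
        "tail": res.tail,
        "statistic_name": res.statistic_name,
        **(res.extra or {}),
    }


def run_pipeline(config: PipelineConfig) -> dict:
    """Execute the configured stages and return the analysis report.

    The report is a plain (JSON-serializable) dict; if ``config.output_dir``
    is set, ``report.json`` and a human-readable ``summary.md`` are written
    there.  Identical config + seed gives a byte-identical report.
    """
    report: dict = {
        "provenance": {
            "config_hash": config.content_hash(),
            "seed": config.seed,
            "stages": list(config.stages),
        }
    }
    stage = "load"
    try:
        epi_raw, endo_raw, tree = _load_inputs(config)

        stage = "preprocess"
        epi, endo, depth = _preprocess(config, epi_raw, endo_raw)
        part = otu_io.partition_otus(epi, endo)
        rich_epi = otu_io.richness(epi)
        rich_endo = otu_io.richness(endo)
        shared_samples = sorted(set(rich_epi) & set(rich_endo))
        t_res = comm.paired_t_log(
            {s: rich_epi[s] for s in shared_samples},
            {s: rich_endo[s] for s in shared_samples},
            tail="greater",
        )
        report["preprocess"] = {
            "min_reads": config.min_reads,
            "rarefaction_depth": depth,
            "partition": dataclasses.asdict(part),
            "richness_epiphyte": rich_epi,
            "richness_endophyte": rich_endo,
            "paired_t_log_richness": _permutation_result_dict(t_res),
        }

        phylo_dist = cophenetic_distances(tree)

        if "community" in config.stages:
            stage = "community"
            seed = stage_seed(config.seed, "community")
            combined = _combined_distance(epi, endo)
            groups = {i: i.split(":", 1)[0] for i in combined.ids}
            anosim_res = comm.anosim(
                combined, groups, n_perm=config.n_perm_anosim, seed=seed
            )
            ord_res = comm.nmds(
                combined, k=2, n_starts=config.nmds_starts, seed=seed
            )
            mantel_out = {}
            for name, table in (("epiphyte", epi), ("endophyte", endo)):
                bc = comm.bray_curtis(comm.hellinger(table), table.sample_ids)
                # similarity = 1 - dissimilarity; expect similarity to fall
                # with phylogenetic distance, i.e. a negative correlation
                sim = comm.DistanceMatrix(
                    bc.ids, np.where(np.eye(bc.n, dtype=bool), 0.0, 1.0 - bc.d)
                )
                res = comm.mantel(
                    sim,
                    phylo_dist.reorder(bc.ids),
                    tail="less",
                    n_perm=config.n_perm_mantel,
                    seed=seed,
                )
                mantel_out[name] = _permutation_result_dict(res)
            report["community"] = {
                "anosim": _permutation_result_dict(anosim_res),
                "nmds_stress": ord_res.stress,
                "nmds_converged": ord_res.converged,
                "mantel": mantel_out,
            }

        if "signal" in config.stages:
            stage = "signal"
            seed = stage_seed(config.seed, "signal")
            out = {}
            for name, rich in (
                ("epiphyte", rich_epi),
                ("endophyte", rich_endo),
            ):
                trait = {t: float(rich[t]) for t in tree.tip_labels}
                k_res = blomberg_k(tree, trait, n_perm=config.n_perm_k, seed=seed)
                l_res = pagel_lambda(tree, trait)
                out[name] = {
                    "blomberg_K": k_res.estimate,
                    "blomberg_K_p": k_res.p_value,
                    "pagel_lambda": l_res.estimate,
                    "pagel_lambda_p": l_res.p_value,
                }
            report["signal"] = out

        networks = {
            "epiphyte": net.InteractionMatrix.from_otu_table(epi),
            "endophyte": net.InteractionMatrix.from_otu_table(endo),
        }

        if "network" in config.stages:
            stage = "network"
            seed = stage_seed(config.seed, "network")
            out = {}
            for name, mat in networks.items():
                metric_fns = {
                    "specialization_H2": net.specialization_h2,
                    "modularity_Q": lambda x: net.modularity(
                        x, n_restarts=config.modularity_restarts_null, seed=seed
                    ).Q,
                    "weighted_connectance": net.weighted_connectance,
                    "WNODF": net.wnodf,
                }
                ensembles = nulls.standardize_many(
                    metric_fns, mat, n_null=config.n_null, seed=seed
                )
                summary = {
                    k: {kk: vv for kk, vv in e.to_dict().items() if kk != "metric"}
                    for k, e in ensembles.items()
                }
                # observed Q deserves the full restart budget; the ensemble's
                # exp/sd come from the cheaper per-null setting
                obs_q = net.modularity(
                    mat, n_restarts=config.modularity_restarts, seed=seed
                ).Q
                mq = summary["modularity_Q"]
                if obs_q > mq["obs"]:
                    mq["obs"] = obs_q
                    if mq["sd_exp"] > 0:
                        mq["z"] = (obs_q - mq["exp"]) / mq["sd_exp"]
                    nv = ensembles["modularity_Q"].null_values
                    mq["p_two_sided"] = float(
                        (1 + np.sum(np.abs(nv - mq["exp"]) >= abs(obs_q - mq["exp"])))
                        / (config.n_null + 1)
                    )
                out[name] = summary
            report["network"] = out

        if "robustness" in config.stages:
            stage = "robustness"
            seed = stage_seed(config.seed, "robustness")
            out = {}
            for name, mat in networks.items():
                per_axis = {}
                for axis in ("plants", "fungi"):
                    curve = rob.simulate_extinctions(
                        mat, primary_axis=axis,
                        n_rep=config.n_rep_extinction, seed=seed,
                    )
                    fit = rob.fit_extinction_curve(curve)
                    per_axis[f"remove_{axis}"] = dataclasses.asdict(fit)
                out[name] = per_axis
            report["robustness"] = out

    except Exception as exc:
        report["failure"] = {"stage": stage, "error": str(exc)}
        if config.output_dir:
            _write_outputs(report, config.output_dir)
        raise RuntimeError(f"pipeline failed at stage {stage!r}: {exc}") from exc

    if config.output_dir:
        _write_outputs(report, config.output_dir)
    return report


def _round_floats(obj, ndigits=10):
    if isinstance(obj, float):
        return round(obj, ndigits)
    if isinstance(obj, dict):
        return {k: _round_floats(v, ndigits) for k, v in obj.items()}
    if isinstance(obj, (list, tuple)):
        return [_round_floats(v, ndigits) for v in obj]
    if isinstance(obj, np.ndarray):
        return _round_floats(obj.tolist(), ndigits)
    if isinstance(obj, (np.integer,)):
        return int(obj)
    if isinstance(obj, (np.floating,)):
        return round(float(obj), ndigits)
    return obj


def _write_outputs(report: dict, output_dir: str) -> None:
    out = Path(output_dir)
    out.mkdir(parents=True, exist_ok=True)
    clean = _round_floats(report)
    (out / "report.json").write_text(json.dumps(clean, indent=2, sort_keys=True))
    (out / "summary.md").write_text(_markdown_summary(clean))


def _markdown_summary(report: dict) -> str:
    lines = ["# Analysis summary", ""]
    pre = report.get("preprocess")
    if pre:
        p = pre["partition"]
        lines += [
            f"- OTUs: {p['n_total']} total; "
            f"{p['n_epiphyte_specific']} ({p['pct_epiphyte_specific']}%) "
            f"epiphyte-specific, {p['n_endophyte_specific']} "
            f"({p['pct_endophyte_specific']}%) endophyte-specific, "
            f"{p['n_shared']} ({p['pct_shared']}%) shared",
            f"- Paired t (log richness, epi > endo): "
            f"t = {pre['paired_t_log_richness']['statistic']:.3f}, "
            f"p = {pre['paired_t_log_richness']['p_value']:.4f}",
        ]
    com = report.get("community")
    if com:
        lines += [
            f"- ANOSIM R = {com['anosim']['statistic']:.3f}, "
            f"p = {com['anosim']['p_value']:.4g}; "
            f"NMDS stress = {com['nmds_stress']:.3f}",
        ]
        for name, res in com["mantel"].items():
            lines.append(
                f"- Mantel ({name}, similarity vs phylo distance): "
                f"r = {res['statistic']:.3f}, p = {res['p_value']:.4g}"
            )
    sig = report.get("signal")
    if sig:
        for name, res in sig.items():
            lines.append(
                f"- Signal in {name} richness: K = {res['blomberg_K']:.3f} "
                f"(p = {res['blomberg_K_p']:.3g}), lambda = "
                f"{res['pagel_lambda']:.3g} (p = {res['pagel_lambda_p']:.3g})"
            )
    nw = report.get("network")
    if nw:
        lines += ["", "| network | metric | obs | z | p |", "|---|---|---|---|---|"]
        for name, metrics in nw.items():
            for metric, e in metrics.items():
                z = "NA" if e["z"] is None else f"{e['z']:.2f}"
                lines.append(
                    f"| {name} | {metric} | {e['obs']:.4f} | {z} | "
                    f"{e['p_two_sided']:.4g} |"
                )
    rb = report.get("robustness")
    if rb:
        lines.append("")
        for name, axes in rb.items():
            for axis, fit in axes.items():
                lines.append(
                    f"- Robustness ({name}, {axis}): R_fitted = "
                    f"{fit['R_fitted']:.3f}, R_empirical = {fit['R_empirical']:.3f}"
                )
    return "\n".join(lines) + "\n"
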