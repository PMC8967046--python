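"""End-to-end orchestration: load/generate -> threshold -> all analyses.

A :class:`PipelineConfig` (buildable from a YAML mapping) drives the full
stage order — similarity matrix in, graph indicators and spectrum, triad
census with null and surprise, energy landscape, mixing pattern, and walk
balance — and writes a single versioned JSON summary plus per-stage CSV
artifacts. Every stochastic stage takes an explicit seed, so a config run
twice produces byte-identical summaries. The triangle list is enumerated
once per (matrix, threshold) and reused by the census, energy and mixing
stages.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import metrics, mixing, triads, walkbalance
from .io import (
    SimilarityMatrix,
    edge_sign_fractions,
    read_similarity_matrix,
    threshold_network,
    write_similarity_matrix,
)
from .synthetic import ProfileModel, generate_profiles, profiles_to_similarity

__all__ = ["PipelineConfig", "run_pipeline", "compare_networks"]

SCHEMA_VERSION = "1"
logger = logging.getLogger("genebalance")


@dataclass
class PipelineConfig:
    """Configuration of a full analysis run.

    Exactly one of ``input_path`` or ``synthetic`` must be given;
    ``synthetic`` is a mapping of :class:`ProfileModel` fields.
    """

    output_dir: str | Path = "genebalance_out"
    input_path: str | Path | None = None
    synthetic: dict | None = None
    triad_threshold: float = 0.05       # census / indicators stage
    walk_threshold: float = 0.2         # walk-balance stage
    null_realizations: int = 20
    null_seed: int = 0
    walk_null_realizations: int = 10
    walk_null_seed: int = 1
    reference_realizations: int = 5
    reference_seed: int = 2
    spectrum_shuffles: int = 10
    spectrum_seed: int = 3
    mixing_bins: int = 50

    def __post_init__(self) -> None:
        if (self.input_path is None) == (self.synthetic is None):
            raise ValueError("give exactly one of input_path or synthetic")
        for t in (self.triad_threshold, self.walk_threshold):
            if not 0.0 <= t <= 1.0:
                raise ValueError(f"threshold {t} outside [0, 1]")

    @classmethod
    def from_yaml(cls, path: str | Path) -> "PipelineConfig":
        with open(path) as fh:
            data = yaml.safe_load(fh)
        return cls(**data)


def _load_similarity(config: PipelineConfig) -> SimilarityMatrix:
    if config.input_path is not None:
        return read_similarity_matrix(config.input_path)
    model = ProfileModel(**config.synthetic)
    return profiles_to_similarity(generate_profiles(model))


def _round_floats(obj, ndigits=10):
    if isinstance(obj, float):
        return round(obj, ndigits)
    if isinstance(obj, dict):
        return {k: _round_floats(v, ndigits) for k, v in obj.items()}
    if isinstance(obj, (list, tuple)):
        return [_round_floats(v, ndigits) for v in obj]
    return obj


def run_pipeline(config: PipelineConfig) -> dict:
    """Run every stage and write ``summary.json`` plus stage artifacts.

    Returns the summary dict. Degenerate stages (no edges / no triads) are
    recorded as skipped with a notice rather than raised.
    """
    out = Path(config.output_dir)
    out.mkdir(parents=True, exist_ok=True)
    summary: dict = {
        "schema_version": SCHEMA_VERSION,
        "config": {
            "output_dir": str(config.output_dir),
            "input_path": str(config.input_path) if config.input_path else None,
            "synthetic": config.synthetic,
            "triad_threshold": config.triad_threshold,
            "walk_threshold": config.walk_threshold,
            "null_realizations": config.null_realizations,
            "null_seed": config.null_seed,
            "walk_null_realizations": config.walk_null_realizations,
            "walk_null_seed": config.walk_null_seed,
            "reference_realizations": config.reference_realizations,
            "reference_seed": config.reference_seed,
            "spectrum_shuffles": config.spectrum_shuffles,
            "spectrum_seed": config.spectrum_seed,
            "mixing_bins": config.mixing_bins,
        },
        "notices": [],
    }

    sim = _load_similarity(config)
    write_similarity_matrix(sim, out / "similarity.tsv")
    logger.info("similarity matrix: %d genes", sim.n_genes)

    net = threshold_network(sim, config.triad_threshold)
    logger.info("thresholded at %.3g: %d nodes, %d edges", config.triad_threshold, net.n_nodes, net.n_edges)

    # --- dataset statistics -------------------------------------------------
    stats: dict = {"nodes": net.n_nodes, "edges": net.n_edges, "threshold": net.threshold}
    if net.n_edges > 0:
        pos, neg = edge_sign_fractions(net)
        stats["positive_edge_fraction"] = pos
        stats["negative_edge_fraction"] = neg
        stats["edge_density"] = net.n_edges / (net.n_nodes * (net.n_nodes - 1) / 2)
    summary["dataset"] = stats

    # --- graph indicators and spectrum --------------------------------------
    if net.n_edges > 0:
        ind = metrics.graph_indicators(
            net, n_realizations=config.reference_realizations, seed=config.reference_seed
        )
        summary["indicators"] = ind.as_dict()
        spec = metrics.spectrum_vs_shuffled(
            sim, n_shuffles=config.spectrum_shuffles, seed=config.spectrum_seed
        )
        summary["spectrum"] = {
            "leading_eigenvalue": float(spec.eigenvalues[0]),
            "bulk_min": spec.bulk_min,
            "bulk_max": spec.bulk_max,
            "n_above_bulk": spec.n_above_bulk,
            "n_below_bulk": spec.n_below_bulk,
        }
        pd.DataFrame({"eigenvalue": spec.eigenvalues}).to_csv(out / "eigenvalues.csv", index=False)
    else:
        summary["notices"].append("no edges retained; indicator and spectrum stages skipped")

    # --- triad census, null, surprise, energy, mixing ------------------------
    tris = triads.triangle_list(net)
    census = triads.count_triads(net, tris=tris)
    summary["triads"] = {
        "total": census.total,
        "balanced": census.balanced,
        "unbalanced": census.unbalanced,
        "counts": {f"T{t}": census.counts[t] for t in range(4)},
    }
    logger.info("census: %d triangles", census.total)

    if census.total > 0:
        null = triads.shuffle_signs(net, M=config.null_realizations, seed=config.null_seed)
        table = triads.surprise(census, null)
        summary["surprise"] = {
            f"T{t}": {
                "count": int(table.counts[t]),
                "p": float(table.p[t]),
                "p0": float(table.p0[t]),
                "expected": float(table.expected[t]),
                "s": None if table.degenerate[t] else float(table.s[t]),
                "s_over_delta": None if table.degenerate[t] else float(table.s_over_delta[t]),
            }
            for t in range(4)
        }
        pd.DataFrame(
            {
                "type": [f"T{t}" for t in range(4)],
                "count": table.counts,
                "p": table.p,
                "p0": table.p0,
                "s": table.s,
                "s_over_delta": table.s_over_delta,
            }
        ).to_csv(out / "surprise.csv", index=False)

        en = triads.energy(net, tris=tris)
        summary["energy"] = {
            "network_energy": en.network_energy,
            "delta_w": en.delta_w,
            "mean_energy_by_type": {
                f"T{t}": None if np.isnan(en.mean_energy_by_type[t]) else float(en.mean_energy_by_type[t])
                for t in range(4)
            },
            "relative_frequency": {f"T{t}": float(en.relative_frequency[t]) for t in range(4)},
        }
        pd.DataFrame(
            {
                "i": en.triangles[:, 0],
                "j": en.triangles[:, 1],
                "k": en.triangles[:, 2],
                "type": en.types,
                "product": en.products,
                "energy": en.energies,
            }
        ).to_csv(out / "triad_energies.csv", index=False)

        mm = mixing.mixing_from_network(en, B=config.mixing_bins)
        summary["mixing"] = {
            "bins": mm.B,
            "type_order": list(mm.type_order),
            "total_link_sharing_pairs": mm.total_pairs,
            "isolation_fraction": mixing.isolation_fraction(en),
        }
        np.savetxt(out / "mixing_grid.tsv", mm.grid(), delimiter="\t")
    else:
        summary["notices"].append("no triads at this threshold; surprise, energy and mixing stages skipped")

    # --- walk balance (own threshold) ----------------------------------------
    wnet = threshold_network(sim, config.walk_threshold)
    wb = walkbalance.walk_balance(wnet)
    shuffled = walkbalance.shuffled_walk_balance(
        wnet, M=config.walk_null_realizations, seed=config.walk_null_seed
    )
    summary["walk_balance"] = {
        "threshold": wnet.threshold,
        "K": wb.K,
        "U": wb.U,
        "U_percent": wb.U_percent,
        "K_shuffled_mean": shuffled.K_mean,
        "K_shuffled_sd": shuffled.K_sd,
        "U_shuffled_mean": shuffled.U_mean,
        "n_highest_balance_nodes": len(wb.highest_balance_nodes),
    }
    pd.DataFrame(
        {
            "gene": list(wnet.gene_ids),
            "K_i": wb.node_balance,
        }
    ).sort_values("K_i", ascending=False, kind="stable").to_csv(out / "node_balance.csv", index=False)

    summary = _round_floats(summary)
    with open(out / "summary.json", "w") as fh:
        json.dump(summary, fh, indent=2, sort_keys=True)
    return summary


def _flatten(d: dict, prefix: str = "") -> dict[str, float]:
    out: dict[str, float] = {}
    for key, val in d.items():
        name = f"{prefix}.{key}" if prefix else str(key)
        if isinstance(val, dict):
            out.update(_flatten(val, name))
        elif isinstance(val, (int, float)) and not isinstance(val, bool) and val is not None:
            out[name] = float(val)
    return out


def compare_networks(report_a: dict, report_b: dict) -> pd.DataFrame:
    """Side-by-side indicator comparison of two pipeline summaries.

    Returns a DataFrame with columns a, b and the signed difference a - b
    for every numeric quantity present in both reports.
    """
    if report_a.get("schema_version") != report_b.get("schema_version"):
        raise ValueError("schema version mismatch between reports")
    fa = _flatten({k: v for k, v in report_a.items() if k not in ("config", "notices")})
    fb = _flatten({k: v for k, v in report_b.items() if k not in ("config", "notices")})
    keys = sorted(set(fa) & set(fb))
    return pd.DataFrame(
        {
            "quantity": keys,
            "a": [fa[k] for k in keys],
            "b": [fb[k] for k in keys],
            "difference": [fa[k] - fb[k] for k in keys],
        }
    ).set_index("quantity")
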