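"""End-to-end orchestration: networks in, merged temporal complexes out.

``run_full`` wires the stages together in memory (dynamic-network
construction -> temporal detection -> cross-time merging); ``run_pipeline``
adds file IO, optional synthetic-input generation, evaluation against a
reference catalogue and a JSON run manifest that records every parameter,
seed and input checksum needed to reproduce the run.
"""

from __future__ import annotations

import hashlib
import json
import logging
import time
from pathlib import Path

import numpy as np

from . import io as tio
from .detection import TSOCD
from .dynamic import (
    DynamicNetworkSeries,
    build_dynamic_networks,
    choose_stable_cutoff,
    classify_stable,
    compute_active_thresholds,
    compute_edge_pcc,
    fit_pcc_gmm,
)
from .evaluation import f_measure, filter_reference
from .merging import MergeNMF, concat_assignments, merge_by_overlap, merge_within_groups
from .synthetic import ScenarioConfig, generate_scenario

logger = logging.getLogger(__name__)

__all__ = ["build_dpn", "run_full", "run_pipeline"]


def build_dpn(
    net: tio.StaticNetwork,
    ge: tio.ExpressionMatrix,
    delta: float = 0.3,
    use_gmm: bool = False,
    gmm_seed: int = 0,
):
    """Construct the dynamic network series from a static network + expression.

    With ``use_gmm=True`` the stable cutoff is the density-crossing point of
    a two-component mixture fitted to the edge PCC values (falling back to
    ``delta``); otherwise ``delta`` is used directly.

    Returns ``(series, info)`` where ``info`` records the PCC table, the
    cutoff used and the mixture fit (or None).
    """
    net, ge = tio.restrict_to_common(net, ge)
    pccs = compute_edge_pcc(net, ge)
    gmm = None
    cutoff = delta
    if use_gmm:
        gmm = fit_pcc_gmm(pccs, seed=gmm_seed)
        cutoff = choose_stable_cutoff(gmm, fallback=delta)
    S = classify_stable(net, pccs, cutoff)
    at = compute_active_thresholds(ge)
    series = build_dynamic_networks(net, ge, S, at, delta=cutoff)
    info = {"pccs": pccs, "delta_used": cutoff, "gmm": gmm, "thresholds": at, "ge": ge}
    return series, info


def run_full(
    net: tio.StaticNetwork,
    ge: tio.ExpressionMatrix,
    *,
    delta: float = 0.3,
    use_gmm: bool = False,
    n_components: int = 1000,
    smooth_weight: float = 2.0**-4,
    lowrank_weight: float = 2.0**4,
    tau: float = 0.3,
    max_iter: int = 150,
    tol: float = 1e-5,
    merge_method: str = "nmf",
    n_groups: int = 1000,
    overlap_threshold: float = 0.65,
    min_size: int = 3,
    seed: int = 0,
) -> dict:
    """Run the full detection pipeline in memory.

    Returns a dict with the dynamic series, the fitted detector, the
    per-time complexes (ID sets, 1-based time labels), the final merged
    complexes and the merge model.
    """
    if merge_method not in ("nmf", "overlap"):
        raise ValueError(f"merge_method must be 'nmf' or 'overlap', got {merge_method!r}")
    model = TSOCD(
        n_components=n_components,
        smooth_weight=smooth_weight,
        lowrank_weight=lowrank_weight,
        tau=tau,
        max_iter=max_iter,
        tol=tol,
        min_size=min_size,
        random_state=seed,
    )
    model._validate()  # reject bad parameters before any compute
    series, info = build_dpn(net, ge, delta=delta, use_gmm=use_gmm, gmm_seed=seed)
    nodes = series.nodes
    model.fit(series.A, S=series.S)

    per_time_sets, labels = [], []
    for t, cxs in enumerate(model.complexes_):
        for c in cxs:
            per_time_sets.append(frozenset(nodes[i] for i in c))
            labels.append(t + 1)
    per_time = tio.ComplexSet(per_time_sets, labels)

    concat = concat_assignments(model.assignments_)
    merger = None
    if merge_method == "nmf":
        merger = MergeNMF(n_groups=n_groups, random_state=seed).fit(concat.Y)
        merged_idx = merge_within_groups(concat, merger.groups_, min_size=min_size)
        final = [frozenset(nodes[i] for i in c) for c in merged_idx]
    else:
        final = merge_by_overlap(per_time_sets, threshold=overlap_threshold)
        final = [c for c in final if len(c) >= min_size]
    # dedup, deterministic order
    uniq: list[frozenset] = []
    for c in final:
        if c not in uniq:
            uniq.append(c)
    return {
        "series": series,
        "info": info,
        "model": model,
        "per_time_complexes": per_time,
        "final_complexes": tio.ComplexSet(uniq),
        "merger": merger,
    }


def _sha256(path) -> str:
    h = hashlib.sha256()
    with open(path, "rb") as fh:
        for chunk in iter(lambda: fh.read(1 << 16), b""):
            h.update(chunk)
    return h.hexdigest()


def run_pipeline(config: dict, out_dir) -> dict:
    """File-level pipeline driver; returns (and writes) the run manifest.

    ``config`` keys: either ``edges``/``expression`` file paths or a
    ``synthetic`` section (ScenarioConfig fields); optional ``reference``
    complex file or ``evaluate_against_truth: true`` for synthetic runs;
    optional overrides of any ``run_full`` keyword under ``params``.
    """
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    params = dict(config.get("params", {}))
    params.setdefault("seed", int(config.get("seed", 0)))
    checksums = {}

    gt = None
    if "synthetic" in config:
        cfg = ScenarioConfig(**{**config["synthetic"], "seed": params["seed"]})
        net, ge, gt = generate_scenario(cfg)
        tio.write_edge_list(net, out / "edges.tsv")
        tio.write_expression(ge, out / "expr.tsv")
        tio.write_complexes(gt.per_time_complex_set(), out / "planted_per_time.tsv")
        tio.write_complexes(tio.ComplexSet(gt.complexes), out / "planted_complexes.tsv")
    else:
        for key in ("edges", "expression"):
            if key not in config:
                raise FileNotFoundError(f"stage 'inputs': missing {key!r} in config")
        net = tio.read_edge_list(config["edges"])
        ge = tio.read_expression(
            config["expression"], average_cycles=bool(config.get("average_cycles", False))
        )
        checksums["edges"] = _sha256(config["edges"])
        checksums["expression"] = _sha256(config["expression"])

    result = run_full(net, ge, **params)

    tio.write_complexes(result["per_time_complexes"], out / "complexes_per_time.tsv")
    tio.write_complexes(result["final_complexes"], out / "complexes_final.tsv")

    report = None
    if config.get("reference"):
        ref = tio.read_complexes(config["reference"], min_size=3)
        checksums["reference"] = _sha256(config["reference"])
        ref_sets = filter_reference(ref, result["series"].nodes)
        report = f_measure(result["final_complexes"], ref_sets, omega=float(config.get("omega", 0.25)))
    elif gt is not None and config.get("evaluate_against_truth", True):
        report = f_measure(result["final_complexes"], gt.complexes, omega=float(config.get("omega", 0.25)))
    if report is not None:
        (out / "evaluation.json").write_text(json.dumps(report.as_dict(), indent=2))

    trace = result["model"].objective_trace_
    manifest = {
        "config": {k: v for k, v in config.items() if k != "params"},
        "params": {k: (v if isinstance(v, (int, float, str, bool)) else str(v)) for k, v in params.items()},
        "seed": params["seed"],
        "delta_used": result["info"]["delta_used"],
        "input_checksums": checksums,
        "n_nodes": len(result["series"].nodes),
        "n_times": result["series"].n_times,
        "objective_trace": {
            "first": float(trace[0]),
            "last": float(trace[-1]),
            "n_sweeps": int(len(trace) - 1),
            "n_outer_iter": int(result["model"].n_iter_),
        },
        "n_per_time_complexes": len(result["per_time_complexes"]),
        "n_final_complexes": len(result["final_complexes"]),
        "evaluation": report.as_dict() if report is not None else None,
        "outputs": sorted(p.name for p in out.iterdir()),
        "timestamp": time.strftime("%Y-%m-%dT%H:%M:%S"),
    }
    (out / "manifest.json").write_text(json.dumps(manifest, indent=2))
    result["manifest"] = manifest
    return result
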