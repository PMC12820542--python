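"""End-to-end orchestration: records in, report bundle out.

:func:`run_full_analysis` reads a path-record CSV (optionally harmonizing
construct names through a merge map), computes the weight table, pools
every path with enough usable β coefficients, runs the publication-bias
diagnostics and the China-vs-rest subgroup comparison on the most-examined
path, builds the theory graphs, and writes everything plus a checksummed
run manifest to the output directory. Outputs are pure functions of the
inputs and the config; manifests carry no timestamps, so identical runs
are byte-identical.
"""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import asdict, dataclass, field
from pathlib import Path

from . import __version__
from .bias import egger_test, funnel_data, trim_and_fill
from .errors import InsufficientDataError, MetaweightError
from .graphs import build_theory_graph, export_graph, load_theory_vocabulary
from .pooling import PoolResult, china_vs_rest, pool_random, pool_subgroups
from .records import canonicalize, group_paths, read_merge_map, read_path_records
from .transforms import effects_from_records
from .weights import weight_table, write_weight_table

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class RunConfig:
    """All knobs of a full run; the defaults reproduce the published
    analysis choices (inclusion at 3 examinations, 95% normal CIs, λ=1,
    Egger flag at p<.10, L0 trim-and-fill, China-vs-rest subgroups)."""

    records_file: str | Path = ""
    merge_map_file: str | Path | None = None
    out_dir: str | Path = "report"
    min_examinations: int = 3
    conf_level: float = 0.95
    lam: int = 1
    egger_alpha: float = 0.10
    trimfill_estimator: str = "L0"
    bias_path: tuple[str, str] | None = None  # default: most-examined path
    seed: int = 0
    log_level: str = "INFO"


def _sha256(path: Path) -> str:
    return hashlib.sha256(path.read_bytes()).hexdigest()


def _fmt_p(p: float) -> str:
    """Report-layer p-value style: '<.001' below, else 2–3 decimals."""
    if p < 0.001:
        return "<.001"
    s = f"{p:.3f}" if p < 0.01 else f"{p:.2f}"
    return s.lstrip("0") if s.startswith("0.") else s


def run_full_analysis(config: RunConfig) -> dict:
    """Run every stage; returns the manifest (also written to disk)."""
    logging.basicConfig(level=config.log_level)
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)

    records = read_path_records(config.records_file)
    logger.info("read %d path records", len(records))
    if config.merge_map_file:
        records = canonicalize(records, read_merge_map(config.merge_map_file))

    groups = group_paths(records, min_examinations=config.min_examinations)
    logger.info("retained %d paths after the inclusion rule", len(groups))

    # --- weight table -----------------------------------------------------
    wtable = weight_table(groups)
    write_weight_table(wtable, out / "weight_table.csv")

    # --- per-path meta-analysis ------------------------------------------
    pools: dict[tuple[str, str], PoolResult] = {}
    meta_lines = [
        "outcome,predictor,k,r,ci_low,ci_high,Q,zscore,p,i2,tau2"
    ]
    contrib_lines = ["outcome,predictor,dataset_id,z,se_z,n,q_component"]
    for g in groups:
        effects = effects_from_records(g.records, lam=config.lam)
        if len(effects) < 2:
            logger.info(
                "path %s -> %s: %d usable beta(s); weight analysis only",
                g.predictor,
                g.outcome,
                len(effects),
            )
            continue
        pool = pool_random(effects, conf_level=config.conf_level)
        pools[(g.predictor, g.outcome)] = pool
        meta_lines.append(
            f"{g.outcome},{g.predictor},{pool.k},{pool.r:.3f},"
            f"{pool.ci_r[0]:.3f},{pool.ci_r[1]:.3f},{pool.Q:.3f},"
            f"{pool.zscore:.3f},{_fmt_p(pool.p)},{pool.i2:.3f},{pool.tau2:.5f}"
        )
        for e, c in zip(effects, pool.contributions):
            contrib_lines.append(
                f"{g.outcome},{g.predictor},{c.dataset_id},{e.z:.6f},"
                f"{e.se_z:.6f},{e.n},{c.q_component:.6f}"
            )
    (out / "meta_table.csv").write_text("\n".join(meta_lines) + "\n")
    (out / "contributions.csv").write_text("\n".join(contrib_lines) + "\n")

    # --- bias diagnostics on the focal path -------------------------------
    focal = config.bias_path
    if focal is None and groups:
        candidates = [g for g in groups if (g.predictor, g.outcome) in pools]
        if candidates:
            focal_group = max(
                candidates, key=lambda g: (g.E, g.predictor, g.outcome)
            )
            focal = (focal_group.predictor, focal_group.outcome)
    bias_report = {}
    if focal is not None and focal in pools:
        group = next(
            g for g in groups if (g.predictor, g.outcome) == focal
        )
        effects = effects_from_records(group.records, lam=config.lam)
        pooled = pools[focal]
        try:
            egger = egger_test(effects)
            tf = trim_and_fill(effects, estimator=config.trimfill_estimator)
            funnel = funnel_data(effects, pooled)
            subgroups = pool_subgroups(effects, grouping=china_vs_rest)
            bias_report = {
                "path": list(focal),
                "egger": {
                    "intercept": egger.intercept,
                    "intercept_se": egger.intercept_se,
                    "slope": egger.slope,
                    "slope_se": egger.slope_se,
                    "t_intercept": egger.t_intercept,
                    "t_slope": egger.t_slope,
                    "df": egger.df,
                    "p_intercept": egger.p_intercept,
                    "p_slope": egger.p_slope,
                    "asymmetry_flagged": egger.p_intercept < config.egger_alpha,
                },
                "trim_and_fill": {
                    "k0": tf.k0,
                    "side": tf.side,
                    "adjusted_r": tf.adjusted.r,
                    "unadjusted_r": pooled.r,
                },
                "funnel_points": len(funnel.points),
                "subgroups": {
                    label: {
                        "k": p.k,
                        "r": p.r,
                        "ci_r": list(p.ci_r),
                        "p": p.p,
                        "i2": p.i2,
                    }
                    for label, p in subgroups
                },
            }
        except (InsufficientDataError, MetaweightError) as exc:
            logger.warning("bias diagnostics skipped for %s: %s", focal, exc)
            bias_report = {"path": list(focal), "error": str(exc)}
        (out / "bias_report.json").write_text(
            json.dumps(bias_report, indent=2, sort_keys=True) + "\n"
        )

    # --- theory graphs ----------------------------------------------------
    graph_dir = out / "graphs"
    graph_dir.mkdir(exist_ok=True)
    for theory, vocab in load_theory_vocabulary().items():
        graph = build_theory_graph(
            theory, [tuple(e) for e in vocab["edges"]], wtable, pools
        )
        safe = theory.replace("+", "_")
        (graph_dir / f"{safe}.json").write_text(export_graph(graph, "json"))
        (graph_dir / f"{safe}.dot").write_text(export_graph(graph, "dot"))

    # --- manifest ----------------------------------------------------------
    outputs = sorted(
        p for p in out.rglob("*") if p.is_file() and p.name != "manifest.json"
    )
    manifest = {
        "version": __version__,
        "config": {
            k: (str(v) if isinstance(v, Path) else v)
            for k, v in asdict(config).items()
        },
        "inputs": {
            "records_file": _sha256(Path(config.records_file)),
            "merge_map_file": (
                _sha256(Path(config.merge_map_file))
                if config.merge_map_file
                else None
            ),
        },
        "counts": {
            "records": len(records),
            "paths": len(groups),
            "pooled_paths": len(pools),
        },
        "outputs": {str(p.relative_to(out)): _sha256(p) for p in outputs},
    }
    (out / "manifest.json").write_text(
        json.dumps(manifest, indent=2, sort_keys=True) + "\n"
    )
    return manifest
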