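"""One-command orchestration: simulate/load -> lag -> fit -> summarise -> export.

Also provides parameter-recovery evaluation against a simulation ground
truth: for each of the three networks the displayed-edge set is compared
with the true nonzero structure (sensitivity / specificity) and the
estimated weights are correlated with the true ones.
"""

from __future__ import annotations

import json
import logging
import sys
import zlib
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import __version__
from .ema_data import (
    BeepSchedule,
    EMADataset,
    ItemSpec,
    compliance_rate,
    describe,
    read_ema_csv,
    stress_affect_eating_items,
    write_ema_csv,
)
from .lag_design import build_lagged, person_statistics
from .network_estimation import (
    BetweenNetwork,
    ContemporaneousNetwork,
    TemporalNetwork,
    fit_between,
    fit_contemporaneous,
    fit_temporal,
    pcor_from_precision,
)
from .network_summary import centrality, display_edges, export_network, zscale
from .synthetic_data import SimulationConfig, SimulationTruth, make_truth, simulate_dataset

__all__ = ["PipelineConfig", "PipelineResult", "RecoveryReport", "run_pipeline", "evaluate_recovery"]

log = logging.getLogger("emanet")


def _stage(name: str) -> None:
    log.info("==== %s ====", name)


def stage_seed(master_seed: int, stage: str) -> int:
    """Deterministic per-stage seed derived from the master seed (< 2^31)."""
    ss = np.random.SeedSequence([master_seed, zlib.crc32(stage.encode())])
    return int(ss.generate_state(1)[0] % (2**31))


@dataclass
class PipelineConfig:
    """Everything one run needs; fully serialisable to YAML/JSON."""

    seed: int = 0
    # input: either a dataset path or a simulation
    dataset_path: str | None = None
    n_items: int = 15
    use_study_items: bool = True
    n_persons: int = 84
    beeps_per_day: int = 4
    n_days: int = 14
    missing_beep_rate: float = 0.15
    eating_item_missing_rate: float = 0.223
    edge_density: float = 0.2
    weight_low: float = 0.1
    weight_high: float = 0.3
    clip_to_range: bool = False
    # estimation / display
    standardize: bool = True
    pvalue_method: str = "normal"
    p_threshold: float = 0.05
    r_threshold: float = 0.1
    rule: str = "or"
    include_self_loops: bool = False
    mad_constant: float = 1.4826
    # output
    outdir: str = "emanet_output"
    log_level: str = "INFO"

    def schedule(self) -> BeepSchedule:
        if self.beeps_per_day == 4:
            return BeepSchedule(beeps_per_day=4, n_days=self.n_days)
        return BeepSchedule(
            beeps_per_day=self.beeps_per_day,
            n_days=self.n_days,
            prompt_labels=tuple(f"t{i + 1}" for i in range(self.beeps_per_day)),
        )

    def to_yaml(self, path=None) -> str:
        text = yaml.safe_dump(asdict(self), sort_keys=False)
        if path is not None:
            Path(path).write_text(text)
        return text

    @classmethod
    def from_yaml(cls, path) -> "PipelineConfig":
        doc = yaml.safe_load(Path(path).read_text()) or {}
        valid = {f for f in cls.__dataclass_fields__}
        unknown = set(doc) - valid
        if unknown:
            raise ValueError(f"unknown config fields: {sorted(unknown)}")
        return cls(**doc)


@dataclass
class PipelineResult:
    """In-memory bundle of one pipeline run."""

    config: PipelineConfig
    dataset: EMADataset
    descriptives: pd.DataFrame
    compliance: float
    temporal: TemporalNetwork
    contemporaneous: ContemporaneousNetwork
    between: BetweenNetwork
    edge_lists: dict
    centralities: dict
    diagnostics: pd.DataFrame
    truth: SimulationTruth | None = None
    outdir: Path | None = None


def run_pipeline(config: PipelineConfig, write: bool = True) -> PipelineResult:
    """Run the full analysis; deterministic given config (incl. seed).

    Stages: load or simulate the dataset; descriptive statistics and
    compliance; within-day lagged design; node-wise multilevel lag-1
    models; between-subject and contemporaneous networks; display rules
    and centralities; export of every artifact plus a run manifest and the
    resolved configuration.
    """
    logging.basicConfig(
        stream=sys.stderr,
        level=getattr(logging, config.log_level.upper(), logging.INFO),
        format="%(asctime)s %(name)s %(levelname)s %(message)s",
    )
    truth = None
    if config.dataset_path is not None:
        _stage("load dataset")
        if config.use_study_items:
            items = stress_affect_eating_items()
        else:
            # generic dataset: one unbounded item per non-index column
            header = pd.read_csv(config.dataset_path, nrows=0).columns
            items = [
                ItemSpec(c, c, "other", -np.inf, np.inf)
                for c in header
                if c not in ("person_id", "day", "beep")
            ]
        dataset = read_ema_csv(config.dataset_path, schedule=config.schedule(), items=items)
    else:
        _stage("simulate dataset")
        names = (
            [it.name for it in stress_affect_eating_items()]
            if config.use_study_items and config.n_items == 15
            else None
        )
        truth = make_truth(
            m=config.n_items,
            edge_density=config.edge_density,
            weight_low=config.weight_low,
            weight_high=config.weight_high,
            seed=stage_seed(config.seed, "truth"),
            item_names=names,
        )
        sim_config = SimulationConfig(
            n_persons=config.n_persons,
            schedule=config.schedule(),
            missing_beep_rate=config.missing_beep_rate,
            eating_item_missing_rate=config.eating_item_missing_rate,
            seed=stage_seed(config.seed, "simulate"),
            clip_to_range=config.clip_to_range,
        )
        dataset = simulate_dataset(truth, sim_config)
    log.info("dataset: %d persons x %d occasions, %d items",
             dataset.n_persons, dataset.schedule.n_occasions, len(dataset.items))

    _stage("descriptives")
    desc = describe(dataset, mad_constant=config.mad_constant)
    comp = compliance_rate(dataset)
    log.info("compliance: %.1f%%", 100 * comp.overall)

    _stage("lagged design")
    means = person_statistics(dataset)
    design = build_lagged(dataset, means)
    if design.is_empty:
        raise RuntimeError(
            "empty lagged design: no usable within-day (t-1 -> t) pairs "
            f"({dataset.n_persons} persons, compliance {100 * comp.overall:.1f}%)"
        )
    log.info("lagged design: %d rows", len(design))

    _stage("temporal network (node-wise mixed models)")
    fit = fit_temporal(
        design, means, standardize=config.standardize, pvalue_method=config.pvalue_method
    )
    n_fallback = int(fit.temporal.fallback.sum())
    if n_fallback:
        log.warning("%d node-model(s) fell back to OLS", n_fallback)

    _stage("between-subject network")
    between = fit_between(fit)

    _stage("contemporaneous network")
    contemp = fit_contemporaneous(fit.residuals, item_names=design.item_names)

    _stage("display rules and centralities")
    networks = {"temporal": fit.temporal, "contemporaneous": contemp, "between": between}
    edge_lists = {
        name: display_edges(
            net, p_threshold=config.p_threshold,
            r_threshold=config.r_threshold, rule=config.rule,
        )
        for name, net in networks.items()
    }
    centralities = {
        name: zscale(centrality(net, include_self_loops=config.include_self_loops))
        for name, net in networks.items()
    }

    result = PipelineResult(
        config=config,
        dataset=dataset,
        descriptives=desc,
        compliance=comp.overall,
        temporal=fit.temporal,
        contemporaneous=contemp,
        between=between,
        edge_lists=edge_lists,
        centralities=centralities,
        diagnostics=fit.diagnostics.table,
        truth=truth,
    )
    if write:
        result.outdir = _write_outputs(result)
    return result


def _write_outputs(result: PipelineResult) -> Path:
    _stage("export")
    config = result.config
    outdir = Path(config.outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    config.to_yaml(outdir / "config_resolved.yaml")
    write_ema_csv(result.dataset, outdir / "dataset.csv")
    result.descriptives.to_csv(outdir / "descriptives.csv")
    result.diagnostics.to_csv(outdir / "fit_diagnostics.csv")
    groups = {it.name: it.group for it in result.dataset.items}
    networks = {
        "temporal": result.temporal,
        "contemporaneous": result.contemporaneous,
        "between": result.between,
    }
    for name, net in networks.items():
        export_network(net, outdir / f"{name}_matrix.csv", "matrix-csv")
        export_network(net, outdir / f"{name}.json", "structured-document", node_groups=groups)
        export_network(net, outdir / f"{name}.graphml", "graphml", node_groups=groups)
        export_network(result.edge_lists[name], outdir / f"{name}_edges.csv", "edgelist-csv")
        result.centralities[name].to_csv(outdir / f"{name}_centrality.csv")
    if result.truth is not None:
        result.truth.to_json(outdir / "truth.json")
    manifest = {
        "software": f"emanet {__version__}",
        "seed": config.seed,
        "n_persons": result.dataset.n_persons,
        "n_items": len(result.dataset.items),
        "compliance": result.compliance,
        "artifacts": sorted(p.name for p in outdir.iterdir()),
    }
    (outdir / "manifest.json").write_text(json.dumps(manifest, indent=2))
    log.info("outputs written to %s", outdir)
    return outdir


# ---------------------------------------------------------------------------
# recovery evaluation
# ---------------------------------------------------------------------------

TRUE_ZERO_TOL = 1e-8


@dataclass
class RecoveryReport:
    """Per-network recovery against a simulation truth.

    sensitivity = displayed true edges / true edges; specificity =
    non-displayed true zeros / true zeros; weight_correlation = Pearson
    correlation of true and estimated weights over the compared entries.
    NaN marks undefined quantities (no true edges, constant weights).
    """

    table: pd.DataFrame
    scenario: dict = field(default_factory=dict)

    def __getitem__(self, key):
        return self.table.loc[key]


def _recovery_row(true_mat, est_mat, displayed_mask, include_diagonal):
    m = true_mat.shape[0]
    off = ~np.eye(m, dtype=bool)
    sel = off | np.eye(m, dtype=bool) if include_diagonal else off
    t = true_mat[sel]
    e = est_mat[sel]
    shown = displayed_mask[sel]
    nonzero = np.abs(t) > TRUE_ZERO_TOL
    ok = ~np.isnan(e)
    tp = np.sum(nonzero & shown & ok)
    fn = np.sum(nonzero & ~(shown & ok))
    fp = np.sum(~nonzero & shown & ok)
    tn = np.sum(~nonzero & ~(shown & ok))
    sens = tp / (tp + fn) if (tp + fn) else np.nan
    spec = tn / (tn + fp) if (tn + fp) else np.nan
    if ok.sum() >= 2 and np.std(t[ok]) > 0 and np.std(e[ok]) > 0:
        corr = float(np.corrcoef(t[ok], e[ok])[0, 1])
    else:
        corr = np.nan
    return sens, spec, corr, int(nonzero.sum()), int((~nonzero).sum())


def _displayed_mask(edge_list, items, directed):
    m = len(items)
    pos = {n: i for i, n in enumerate(items)}
    mask = np.zeros((m, m), dtype=bool)
    for r in edge_list.displayed().itertuples(index=False):
        if directed:
            mask[pos[r.to_node], pos[r.from_node]] = True
        else:
            mask[pos[r.from_node], pos[r.to_node]] = True
            mask[pos[r.to_node], pos[r.from_node]] = True
    return mask


def evaluate_recovery(
    truth: SimulationTruth,
    result: PipelineResult | None = None,
    *,
    temporal: TemporalNetwork | None = None,
    contemporaneous: ContemporaneousNetwork | None = None,
    between: BetweenNetwork | None = None,
    edge_lists: dict | None = None,
    include_temporal_diagonal: bool = False,
    scenario: dict | None = None,
) -> RecoveryReport:
    """Compare estimated networks and displayed edges with the truth.

    True edges are the exactly-nonzero entries of the generative matrices
    (B; the partial correlations implied by Theta and by Sigma_between).
    Weight correlations are computed over off-diagonal entries; for the
    temporal network the autoregressive diagonal can be included.
    """
    if result is not None:
        temporal = result.temporal
        contemporaneous = result.contemporaneous
        between = result.between
        edge_lists = result.edge_lists
    if temporal is None or contemporaneous is None or between is None or edge_lists is None:
        raise ValueError("need either a PipelineResult or all three networks plus edge lists")
    items = truth.item_names
    if list(temporal.item_names) != items:
        raise ValueError(
            f"node labels differ: truth {items[:3]}..., estimate {temporal.item_names[:3]}..."
        )
    truths = {
        "temporal": truth.B,
        "contemporaneous": truth.contemporaneous_pcor(),
        "between": truth.between_pcor(),
    }
    estimates = {
        "temporal": temporal.weights.to_numpy(),
        "contemporaneous": contemporaneous.weights.to_numpy(),
        "between": between.weights.to_numpy(),
    }
    rows = {}
    for name in truths:
        mask = _displayed_mask(edge_lists[name], items, directed=(name == "temporal"))
        rows[name] = _recovery_row(
            truths[name],
            estimates[name],
            mask,
            include_diagonal=(name == "temporal" and include_temporal_diagonal),
        )
    table = pd.DataFrame(
        rows, index=["sensitivity", "specificity", "weight_correlation", "n_true_edges", "n_true_zeros"]
    ).T
    return RecoveryReport(table=table, scenario=scenario or {})
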