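"""End-to-end study orchestration.

Reads per-wave wide CSV files (one row per subject, ordinal item columns,
optional continuous/binary covariates), reduces a multi-item self-efficacy
scale to its first principal component, estimates a regularised
partial-correlation network per wave, computes centralities and bootstrap
robustness, and compares waves pairwise (permutation test + descriptive
similarity) on the complete-case subset.  Every number in the output
bundle is reproducible from the config and root seed alone.
"""

from __future__ import annotations

import hashlib
import json
import logging
import time
from dataclasses import dataclass, field
from itertools import combinations
from pathlib import Path

import networkx as nx
import numpy as np
import pandas as pd
import yaml

from .centrality import CentralityTable, centrality_table
from .correlations import OrdinalDataset, correlation_matrix
from .ggm import GGMConfig, GGMNetwork, estimate_network
from .nct import nct_dependent
from .robustness import BootstrapSpec, case_dropping_boot, nonparametric_boot
from .temporal import similarity_report

__all__ = [
    "ItemSpec",
    "StudyConfig",
    "ComponentScore",
    "load_wave",
    "write_wave",
    "gse_component",
    "complete_case_filter",
    "run_study",
]

log = logging.getLogger("sympnet")


@dataclass(frozen=True)
class ItemSpec:
    """One column of the item roster."""

    code: str
    kind: str = "ordinal"  # ordinal | continuous | binary
    n_levels: int = 4
    level_offset: int = 0  # smallest admissible level (e.g. 1 for 1..4 scales)


@dataclass
class StudyConfig:
    """Configuration of a full study run."""

    wave_paths: dict[str, str] = field(default_factory=dict)
    items: list[ItemSpec] = field(default_factory=list)
    network_items: list[str] = field(default_factory=list)
    gse_items: list[str] = field(default_factory=list)
    gse_code: str = "gse"
    covariates: list[str] = field(default_factory=list)
    ggm: GGMConfig = field(default_factory=GGMConfig)
    bootstrap: BootstrapSpec = field(default_factory=BootstrapSpec)
    n_perm: int = 1000
    run_bootstraps: bool = True
    out_dir: str = "sympnet_output"
    seed: int = 0
    log_level: str = "INFO"

    @classmethod
    def from_file(cls, path: str | Path) -> "StudyConfig":
        raw = yaml.safe_load(Path(path).read_text())
        items = [ItemSpec(**it) for it in raw.pop("items", [])]
        ggm = GGMConfig(**raw.pop("ggm", {}))
        boot = raw.pop("bootstrap", {})
        if "drop_proportions" in boot:
            boot["drop_proportions"] = tuple(boot["drop_proportions"])
        bootstrap = BootstrapSpec(**boot)
        return cls(items=items, ggm=ggm, bootstrap=bootstrap, **raw)

    def digest(self) -> str:
        payload = json.dumps({
            "waves": self.wave_paths, "items": [vars(i) for i in self.items],
            "network_items": self.network_items, "gse_items": self.gse_items,
            "covariates": self.covariates, "ggm": vars(self.ggm) | {},
            "bootstrap": {k: list(v) if isinstance(v, tuple) else v
                          for k, v in vars(self.bootstrap).items()},
            "n_perm": self.n_perm, "seed": self.seed,
        }, sort_keys=True, default=str)
        return hashlib.sha256(payload.encode()).hexdigest()[:16]


@dataclass
class ComponentScore:
    """First-principal-component score of a multi-item scale."""

    scores: np.ndarray  # per subject; NaN where items were incomplete
    loadings: np.ndarray
    variance_explained: float  # percent of total variance, in (0, 100]


# ---------------------------------------------------------------------------
# I/O
# ---------------------------------------------------------------------------

def load_wave(path: str | Path, roster: list[ItemSpec],
              time_label: str = "") -> OrdinalDataset:
    """Read one wave from wide CSV and validate it against the roster.

    Expects columns ``subject_id`` (unique), optionally ``time``, and one
    column per roster item.  Ordinal/binary levels outside
    [offset, offset + n_levels) are rejected with the offending cell named.
    Levels are shifted to start at 0 internally.
    """
    df = pd.read_csv(path)
    if "subject_id" not in df.columns:
        raise ValueError(f"{path}: missing subject_id column")
    if df["subject_id"].duplicated().any():
        dupes = df.loc[df["subject_id"].duplicated(), "subject_id"].tolist()
        raise ValueError(f"{path}: duplicate subject IDs {dupes}")
    missing_cols = [it.code for it in roster if it.code not in df.columns]
    if missing_cols:
        raise ValueError(f"{path}: roster columns absent: {missing_cols}")
    if not time_label and "time" in df.columns and len(df):
        time_label = str(df["time"].iloc[0])

    values = np.empty((len(df), len(roster)))
    for j, it in enumerate(roster):
        col = pd.to_numeric(df[it.code], errors="coerce").to_numpy(dtype=float)
        if it.kind in ("ordinal", "binary"):
            n_levels = 2 if it.kind == "binary" else it.n_levels
            obs = ~np.isnan(col)
            bad = obs & ((col < it.level_offset)
                         | (col >= it.level_offset + n_levels)
                         | (col != np.floor(col)))
            if bad.any():
                row = int(np.nonzero(bad)[0][0])
                raise ValueError(
                    f"{path}: invalid level {col[row]!r} in column {it.code!r}, "
                    f"row {row} (allowed {it.level_offset}.."
                    f"{it.level_offset + n_levels - 1})")
            col = col - it.level_offset
        values[:, j] = col

    ds = OrdinalDataset(values=values, item_codes=[it.code for it in roster],
                        item_kind=[it.kind for it in roster],
                        time_label=time_label,
                        subject_ids=df["subject_id"].to_numpy())
    counts = ds.observed_mask().sum(axis=0)
    log.info("loaded %s: %d subjects, %d items, observed counts %s..%s",
             path, ds.n_subjects, ds.n_items, counts.min(), counts.max())
    return ds


def write_wave(ds: OrdinalDataset, path: str | Path) -> None:
    """Write a dataset as wide CSV (subject_id, time, item columns)."""
    ds.to_frame().to_csv(path, index=False)


# ---------------------------------------------------------------------------
# Self-efficacy principal component
# ---------------------------------------------------------------------------

def gse_component(gse_items: np.ndarray) -> ComponentScore:
    """First principal component of a multi-item scale.

    Items are column-standardised over complete rows; the component sign is
    fixed so the loading sum is positive; scores have mean zero over the
    estimation sample (incomplete rows get NaN).  Returns the percentage of
    total variance the first component explains.
    """
    X = np.asarray(gse_items, dtype=float)
    if X.ndim != 2:
        raise ValueError("gse_items must be 2-D (subjects x items)")
    complete = ~np.isnan(X).any(axis=1)
    if complete.sum() < 2:
        raise ValueError("need at least 2 complete rows for the component")
    Xc = X[complete]
    sd = np.std(Xc, axis=0, ddof=1)
    if np.any(sd == 0):
        bad = int(np.nonzero(sd == 0)[0][0])
        raise ValueError(f"constant item at column {bad}; component undefined")
    Z = (Xc - Xc.mean(axis=0)) / sd

    # PCA via SVD of the standardized matrix
    _, s, Vt = np.linalg.svd(Z, full_matrices=False)
    loadings = Vt[0]
    if loadings.sum() < 0:
        loadings = -loadings
    var_explained = float(100.0 * s[0] ** 2 / np.sum(s ** 2))

    scores = np.full(X.shape[0], np.nan)
    raw = Z @ loadings
    scores[complete] = raw - raw.mean()
    return ComponentScore(scores=scores, loadings=loadings,
                          variance_explained=var_explained)


# ---------------------------------------------------------------------------
# Complete cases
# ---------------------------------------------------------------------------

def complete_case_filter(waves: list[OrdinalDataset],
                         item_subset: list[str] | None = None
                         ) -> tuple[list[OrdinalDataset], int]:
    """Retain subjects observed on all listed items at every wave.

    Waves must hold aligned subject IDs.  Returns the filtered waves and
    the retained-subject count; an empty result raises.
    """
    ids0 = waves[0].subject_ids
    for w in waves[1:]:
        if not np.array_equal(w.subject_ids, ids0):
            raise ValueError("waves must hold aligned subject IDs")
    keep = np.ones(len(ids0), dtype=bool)
    for w in waves:
        if item_subset is None:
            cols = slice(None)
        else:
            cols = [w.item_codes.index(c) for c in item_subset]
        keep &= ~np.isnan(w.values[:, cols]).any(axis=1)
    n_kept = int(keep.sum())
    if n_kept == 0:
        raise ValueError("complete-case filter removed every subject")
    out = [OrdinalDataset(values=w.values[keep], item_codes=list(w.item_codes),
                          item_kind=list(w.item_kind), time_label=w.time_label,
                          subject_ids=w.subject_ids[keep]) for w in waves]
    return out, n_kept


# ---------------------------------------------------------------------------
# Orchestration
# ---------------------------------------------------------------------------

def _network_dataset(ds: OrdinalDataset, config: StudyConfig) -> OrdinalDataset:
    """Assemble the estimation dataset: network items, the self-efficacy
    component (standardised, missing rows propagated), then covariates."""
    codes, kinds, cols = [], [], []
    roster = {it.code: it for it in config.items}
    for code in config.network_items:
        j = ds.item_codes.index(code)
        codes.append(code)
        kinds.append(ds.item_kind[j])
        cols.append(ds.values[:, j])
    if config.gse_items:
        idx = [ds.item_codes.index(c) for c in config.gse_items]
        comp = gse_component(ds.values[:, idx])
        sd = np.nanstd(comp.scores, ddof=1)
        codes.append(config.gse_code)
        kinds.append("continuous")
        cols.append(comp.scores / sd if sd > 0 else comp.scores)
    for code in config.covariates:
        j = ds.item_codes.index(code)
        codes.append(code)
        kinds.append(roster[code].kind if code in roster else ds.item_kind[j])
        cols.append(ds.values[:, j])
    return OrdinalDataset(values=np.column_stack(cols), item_codes=codes,
                          item_kind=kinds, time_label=ds.time_label,
                          subject_ids=ds.subject_ids)


def _write_network(net: GGMNetwork, out: Path, stem: str) -> None:
    net.to_frame().to_csv(out / f"{stem}_adjacency.csv")
    net.edge_list().to_csv(out / f"{stem}_edges.csv", index=False)
    G = nx.Graph()
    G.add_nodes_from(net.node_labels)
    for _, row in net.edge_list().iterrows():
        G.add_edge(row.node_i, row.node_j, weight=float(row.weight))
    nx.write_graphml(G, out / f"{stem}.graphml")


def run_study(config: StudyConfig) -> dict:
    """Run the full analysis and write the report bundle to ``out_dir``.

    Per wave: latent correlation matrix, EBIC-glasso network, centrality
    table, and (optionally) edge-weight and case-dropping bootstraps.
    Across waves: paired permutation comparison tests on the complete-case
    subset and a descriptive similarity table.  Returns the summary dict
    that is also written as ``summary.json``.
    """
    logging.basicConfig(level=getattr(logging, config.log_level.upper(), logging.INFO))
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    t_start = time.time()

    waves: dict[str, OrdinalDataset] = {}
    for label, path in config.wave_paths.items():
        waves[label] = load_wave(path, config.items, time_label=label)

    summary: dict = {
        "config_digest": config.digest(),
        "seed": config.seed,
        "waves": {},
        "comparisons": [],
    }

    networks: dict[str, GGMNetwork] = {}
    tables: dict[str, CentralityTable] = {}
    net_data: dict[str, OrdinalDataset] = {}
    for i, (label, ds) in enumerate(waves.items()):
        t0 = time.time()
        nd = _network_dataset(ds, config)
        net_data[label] = nd
        R = correlation_matrix(nd)
        R.to_frame().to_csv(out / f"{label}_correlations.csv")
        (out / f"{label}_thresholds.json").write_text(json.dumps(
            {code: thr.tolist() for code, thr in R.thresholds.items()}, indent=2))
        net = estimate_network(nd, config.ggm)
        networks[label] = net
        _write_network(net, out, f"{label}_network")
        tab = centrality_table(net)
        tables[label] = tab
        tab.to_frame().to_csv(out / f"{label}_centrality.csv", index=False)

        wave_summary = {
            "n_subjects": nd.n_subjects,
            "n_nodes": net.p,
            "n_edges": net.n_edges,
            "lambda_selected": net.lambda_selected,
            "global_strength": net.global_strength,
            "pd_repaired": R.pd_repaired,
        }
        if config.gse_items:
            idx = [ds.item_codes.index(c) for c in config.gse_items]
            wave_summary["gse_variance_explained"] = gse_component(
                ds.values[:, idx]).variance_explained

        if config.run_bootstraps:
            boot_spec = BootstrapSpec(
                n_boot=config.bootstrap.n_boot,
                drop_proportions=config.bootstrap.drop_proportions,
                stability_cor_threshold=config.bootstrap.stability_cor_threshold,
                stability_prob=config.bootstrap.stability_prob,
                seed=config.seed + 1000 * (i + 1),
            )
            ci = nonparametric_boot(nd, boot_spec, config.ggm)
            ci.to_frame().to_csv(out / f"{label}_edge_ci.csv", index=False)
            stab = case_dropping_boot(nd, boot_spec, "strength", config.ggm)
            stab.curve().to_csv(out / f"{label}_stability.csv", index=False)
            wave_summary["strength_cs_coefficient"] = stab.cs_coefficient
        summary["waves"][label] = wave_summary
        log.info("wave %s: p=%d n=%d edges=%d (%.1fs)", label, net.p,
                 nd.n_subjects, net.n_edges, time.time() - t0)

    labels = list(waves.keys())
    if len(labels) >= 2:
        # paired permutation test needs fully observed node vectors
        cc_waves, n_cc = complete_case_filter([net_data[w] for w in labels])
        summary["n_complete_cases"] = n_cc
        for a_i, b_i in combinations(range(len(labels)), 2):
            la, lb = labels[a_i], labels[b_i]
            da, db = cc_waves[a_i], cc_waves[b_i]
            res = nct_dependent(da, db, n_perm=config.n_perm, config=config.ggm,
                                seed=config.seed + 7919 * (a_i * len(labels) + b_i))
            summary["comparisons"].append({"wave_a": la, "wave_b": lb}
                                          | res.summary())
            log.info("NCT %s vs %s: p_structure=%.3f p_strength=%.3f",
                     la, lb, res.summary()["p_structure"],
                     res.summary()["p_strength"])
        sim = similarity_report(networks, tables)
        sim.to_csv(out / "similarity.csv", index=False)
        summary["similarity"] = sim.to_dict(orient="records")
    else:
        log.info("single wave: comparison and similarity stages skipped")

    summary["runtime_seconds"] = round(time.time() - t_start, 2)
    (out / "summary.json").write_text(json.dumps(summary, indent=2, default=float))
    return summary
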