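"""Seeded generators for every input the pipeline consumes.

The generators emulate the statistical structure the analysis assumes —
multi-dataset differential expression with planted consistent signatures, a
connected scale-free interaction network, subpathway gene sets, survival
times driven by a linear predictor over subpathway activities, and IC50
values driven by planted subpathway expression — so every downstream stage
can be exercised with truth labels and no external downloads. All generators
are pure functions of (arguments, seed).

Modeling choices: the network is preferential-attachment (heavy-tailed
degrees, like curated PPI networks); counts are negative binomial with
log-normal gene means (meanlog 4, sdlog 1); survival is exponential
proportional hazards with independent uniform censoring calibrated to a
target censoring rate; methylation is logit-normal in (0,1); copy number is
integer in {-2..2}.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import networkx as nx
import numpy as np
import pandas as pd
from scipy.optimize import brentq
from scipy.special import expit

from .drugnet import DrugScreen
from .errors import InvalidArgumentError
from .netprop import InteractionNetwork
from .prognosis import SurvivalCohort
from .subpathway import Subpathway, SubpathwayCollection

__all__ = [
    "SyntheticTruth",
    "GeneExpressionStudy",
    "generate_network",
    "generate_study",
    "generate_subpathways",
    "generate_survival",
    "generate_activity_matrix",
    "generate_tumor_study",
    "generate_drug_screen",
    "simulate_all",
    "DEFAULT_SIMULATION",
]

#: annotation combinations behind the group labels used in contrasts
GROUP_SPECS = {
    "MicT": {"cell": "microglia", "condition": "tumor"},
    "MacT": {"cell": "macrophage", "condition": "tumor"},
    "MicN": {"cell": "microglia", "condition": "normal"},
}

MEANLOG = 4.0
SDLOG = 1.0


@dataclass
class SyntheticTruth:
    """Ground truth planted into a simulation run."""

    planted_de_genes: dict[str, dict[str, str]] = field(default_factory=dict)
    planted_subpathways: set = field(default_factory=set)
    true_coefficients: dict[str, float] = field(default_factory=dict)
    drug_drivers: dict[str, str] = field(default_factory=dict)

    def to_json(self) -> str:
        return json.dumps(
            {
                "planted_de_genes": self.planted_de_genes,
                "planted_subpathways": sorted(self.planted_subpathways),
                "true_coefficients": self.true_coefficients,
                "drug_drivers": self.drug_drivers,
            },
            indent=2,
        )

    @classmethod
    def from_json(cls, text: str) -> "SyntheticTruth":
        obj = json.loads(text)
        return cls(
            planted_de_genes=obj.get("planted_de_genes", {}),
            planted_subpathways=set(obj.get("planted_subpathways", ())),
            true_coefficients=obj.get("true_coefficients", {}),
            drug_drivers=obj.get("drug_drivers", {}),
        )


@dataclass
class GeneExpressionStudy:
    """Gene x sample matrix with per-sample annotations.

    ``scale_tag`` is "count" (non-negative integers) or "log" (already on a
    log2-like scale). ``sample_annotations`` is indexed by sample id with
    columns cell, condition, batch and group.
    """

    dataset_id: str
    values: pd.DataFrame
    scale_tag: str
    sample_annotations: pd.DataFrame

    def __post_init__(self):
        if self.scale_tag not in ("count", "log"):
            raise InvalidArgumentError(f"scale_tag must be count or log, got {self.scale_tag!r}")
        if self.values.index.hasnans or self.values.index.duplicated().any():
            raise InvalidArgumentError("gene ids must be unique and non-missing")
        missing = set(self.values.columns) - set(self.sample_annotations.index)
        if missing:
            raise InvalidArgumentError(f"samples without annotation: {sorted(missing)[:5]}")
        if self.scale_tag == "count":
            arr = self.values.to_numpy()
            if np.any(arr < 0) or not np.allclose(arr, np.round(arr)):
                raise InvalidArgumentError("count-scale values must be integers >= 0")

    @property
    def genes(self) -> list:
        return list(self.values.index)

    @property
    def samples(self) -> list:
        return list(self.values.columns)

    def log_values(self, pseudocount: float = 1.0) -> pd.DataFrame:
        """Expression on the log2 scale (log2(x + pseudocount) for counts)."""
        if self.scale_tag == "log":
            return self.values
        return np.log2(self.values + pseudocount)

    def group_labels(self) -> pd.Series:
        """Per-sample contrast group label (MicT/MacT/MicN or the condition)."""
        ann = self.sample_annotations
        if "group" in ann.columns:
            return ann.loc[self.samples, "group"]
        labels = {}
        for sample, row in ann.loc[self.samples].iterrows():
            label = row.get("condition", "unknown")
            for name, spec in GROUP_SPECS.items():
                if row.get("cell") == spec["cell"] and row.get("condition") == spec["condition"]:
                    label = name
                    break
            labels[sample] = label
        return pd.Series(labels, name="group").loc[self.samples]


def _gene_ids(n: int) -> list[str]:
    return [f"G{i:05d}" for i in range(n)]


def generate_network(
    n_genes: int, attach: int = 2, evidence_rate: float = 0.8, seed: int = 0
) -> InteractionNetwork:
    """Scale-free (preferential attachment) interaction network over the gene
    universe; each edge carries an evidence count in {1,2,3} with
    P(count >= 2) = evidence_rate."""
    if n_genes < 3:
        raise InvalidArgumentError(f"n_genes must be >= 3, got {n_genes}")
    if attach < 1:
        raise InvalidArgumentError("attach must be >= 1")
    if not (0 <= evidence_rate <= 1):
        raise InvalidArgumentError("evidence_rate must be a probability")
    rng = np.random.default_rng(seed)
    g = nx.barabasi_albert_graph(n_genes, attach, seed=int(rng.integers(2**31)))
    genes = _gene_ids(n_genes)
    g = nx.relabel_nodes(g, dict(enumerate(genes)))
    for u, v in g.edges:
        if rng.random() < evidence_rate:
            g[u][v]["evidence_count"] = int(rng.integers(2, 4))
        else:
            g[u][v]["evidence_count"] = 1
    return InteractionNetwork(g)


def _nb_sample(rng, mean, dispersion, size):
    """Negative binomial draws with var = mean + dispersion * mean^2
    (Poisson when dispersion == 0)."""
    if dispersion == 0:
        return rng.poisson(mean, size=size)
    shape = 1.0 / dispersion
    lam = rng.gamma(shape, np.asarray(mean) / shape, size=size)
    return rng.poisson(lam)


def _infer_comparison_group(design: Mapping[str, int]) -> str:
    keys = list(design)
    if len(keys) != 2:
        raise InvalidArgumentError(f"design must name exactly two groups, got {keys}")
    return f"{keys[0]}/{keys[1]}"


def generate_study(
    dataset_id: str,
    design: Mapping[str, int],
    planted: SyntheticTruth,
    effect_log2fc: float,
    dispersion: float = 0.1,
    seed: int = 0,
    genes: Sequence[str] | None = None,
) -> GeneExpressionStudy:
    """Count-scale two-group study with planted differential expression.

    ``design`` maps two group labels (e.g. MicT, MacT) to sample counts; the
    comparison group is "<first>/<second>" and planted genes of that group are
    shifted by +/- ``effect_log2fc`` (log2 scale) in the first-named group.
    Baseline means are log-normal; counts negative binomial.
    """
    if effect_log2fc < 0:
        raise InvalidArgumentError("effect_log2fc must be >= 0")
    if genes is None:
        raise InvalidArgumentError("a gene universe must be supplied")
    genes = list(genes)
    group = _infer_comparison_group(design)
    plan = planted.planted_de_genes.get(group, {})
    unknown = set(plan) - set(genes)
    if unknown:
        raise InvalidArgumentError(f"planted genes not in the gene universe: {sorted(unknown)[:5]}")

    rng = np.random.default_rng(seed)
    base_mean = rng.lognormal(MEANLOG, SDLOG, size=len(genes))
    gene_pos = {g: i for i, g in enumerate(genes)}

    labels = list(design)
    columns, ann_rows, blocks = [], [], []
    for gi, label in enumerate(labels):
        n = int(design[label])
        mean = base_mean.copy()
        if gi == 0:  # shift planted genes in the first-named group
            for gene, direction in plan.items():
                factor = 2.0**effect_log2fc if direction == "up" else 2.0**-effect_log2fc
                mean[gene_pos[gene]] *= factor
        block = _nb_sample(rng, mean[:, None], dispersion, (len(genes), n))
        blocks.append(block)
        spec = GROUP_SPECS.get(label, {"cell": "bulk", "condition": label.lower()})
        for k in range(n):
            sample = f"{dataset_id}_{label}_{k:02d}"
            columns.append(sample)
            ann_rows.append({"sample": sample, "cell": spec["cell"],
                             "condition": spec["condition"], "batch": dataset_id,
                             "group": label})
    values = pd.DataFrame(np.hstack(blocks), index=genes, columns=columns)
    ann = pd.DataFrame(ann_rows).set_index("sample")
    return GeneExpressionStudy(dataset_id=dataset_id, values=values,
                               scale_tag="count", sample_annotations=ann)


_CLASS_LABELS = ("Metabolism", "Signal transduction", "Immune system",
                 "Cell motility", "Human diseases")


def generate_subpathways(
    n_sets: int,
    size_range: tuple[int, int],
    network: InteractionNetwork,
    seed: int = 0,
    overlap_fraction: float = 0.0,
) -> SubpathwayCollection:
    """Random subpathway gene sets over the network's gene universe.

    ``overlap_fraction`` of the sets are built to share more than 7 genes with
    another set (to exercise crosstalk edges); at 0, no pair shares more than
    7. Each set gets a parent pathway id (~3 subpathways per pathway) and a
    class label.
    """
    lo, hi = size_range
    if lo < 3:
        raise InvalidArgumentError("size_range lower bound must be >= 3")
    if hi < lo:
        raise InvalidArgumentError("size_range must be a valid interval")
    rng = np.random.default_rng(seed)
    genes = np.array(network.genes)
    entries: list[Subpathway] = []
    member_sets: list[set] = []
    n_overlapping = int(round(overlap_fraction * n_sets))
    for i in range(n_sets):
        size = int(rng.integers(lo, hi + 1))
        donors = [s for s in member_sets if len(s) >= 8]
        make_overlap = i <= n_overlapping and bool(donors)
        for _attempt in range(100):
            if make_overlap:
                size_eff = max(size, 9)
                partner = donors[int(rng.integers(len(donors)))]
                shared = set(rng.choice(sorted(partner), size=8, replace=False))
                fill_pool = np.array(sorted(set(genes) - shared))
                extra = rng.choice(fill_pool, size=size_eff - 8, replace=False)
                members = shared | set(extra)
            else:
                members = set(rng.choice(genes, size=size, replace=False))
                if any(len(members & prev) > 7 for prev in member_sets):
                    continue  # keep non-overlap sets genuinely below the threshold
            break
        member_sets.append(members)
        entries.append(
            Subpathway(
                subpathway_id=f"path:{i // 3:04d}_{i % 3 + 1}",
                parent_pathway_id=f"path:{i // 3:04d}",
                class_label=_CLASS_LABELS[(i // 3) % len(_CLASS_LABELS)],
                members=frozenset(members),
            )
        )
    return SubpathwayCollection(entries)


def generate_activity_matrix(
    subpathway_ids: Sequence[str], n_samples: int, seed: int = 0, prefix: str = "S"
) -> pd.DataFrame:
    """Independent standard-normal subpathway x sample activity matrix."""
    rng = np.random.default_rng(seed)
    samples = [f"{prefix}{i:04d}" for i in range(n_samples)]
    return pd.DataFrame(
        rng.standard_normal((len(subpathway_ids), n_samples)),
        index=list(subpathway_ids), columns=samples,
    )


def generate_survival(
    activity: pd.DataFrame,
    true_coefficients: Mapping[str, float],
    baseline_hazard: float = 0.1,
    censor_rate: float = 0.3,
    seed: int = 0,
) -> SurvivalCohort:
    """Exponential proportional-hazards survival from an activity matrix.

    Event rate per sample = baseline_hazard * exp(sum coef * activity).
    Censoring is independent Uniform(0, c_max) with c_max calibrated so the
    expected censored fraction is ``censor_rate``.
    """
    if baseline_hazard <= 0:
        raise InvalidArgumentError("baseline_hazard must be positive")
    if not (0 <= censor_rate < 1):
        raise InvalidArgumentError("censor_rate must be in [0, 1)")
    missing = set(true_coefficients) - set(activity.index)
    if missing:
        raise InvalidArgumentError(f"coefficients reference unknown rows: {sorted(missing)[:5]}")
    rng = np.random.default_rng(seed)
    lp = np.zeros(activity.shape[1])
    for sid, coef in true_coefficients.items():
        lp += coef * activity.loc[sid].to_numpy(dtype=float)
    rate = baseline_hazard * np.exp(lp)
    t_event = rng.exponential(1.0 / rate)
    if censor_rate == 0:
        data = pd.DataFrame({"time": t_event, "event": 1}, index=activity.columns)
        return SurvivalCohort(data)

    def expected_censored(c_max):
        lam = rate
        return float(np.mean((1.0 - np.exp(-lam * c_max)) / (lam * c_max)))

    # expected_censored decreases from 1 (c_max -> 0) to 0 (c_max -> inf)
    lo, hi = 1e-9, 1.0
    while expected_censored(hi) > censor_rate:
        hi *= 2.0
        if hi > 1e12:
            break
    c_max = brentq(lambda c: expected_censored(c) - censor_rate, lo, hi)
    t_cens = rng.uniform(0, c_max, size=len(t_event))
    time = np.minimum(t_event, t_cens)
    event = (t_event <= t_cens).astype(int)
    data = pd.DataFrame({"time": time, "event": event}, index=activity.columns)
    return SurvivalCohort(data)


def generate_tumor_study(
    dataset_id: str,
    n_samples: int,
    genes: Sequence[str],
    collection: SubpathwayCollection,
    signal_subpathways: Iterable[str],
    factor_sd: float = 1.0,
    dispersion: float = 0.1,
    seed: int = 0,
) -> tuple[GeneExpressionStudy, pd.DataFrame]:
    """Bulk tumor cohort whose signal-subpathway members co-vary per sample.

    Each signal subpathway gets a per-sample latent factor (sd ``factor_sd``)
    added to its member genes on the log2 scale, so its ssGSEA activity tracks
    the factor. Returns (study, factor matrix) — the factors are the ground
    truth behind downstream activity-driven survival.
    """
    rng = np.random.default_rng(seed)
    genes = list(genes)
    gene_pos = {g: i for i, g in enumerate(genes)}
    base_mean = rng.lognormal(MEANLOG, SDLOG, size=len(genes))
    signal_subpathways = list(signal_subpathways)
    factors = rng.normal(0, factor_sd, size=(len(signal_subpathways), n_samples))
    log2_shift = np.zeros((len(genes), n_samples))
    for si, sid in enumerate(signal_subpathways):
        for g in collection[sid].members:
            if g in gene_pos:
                log2_shift[gene_pos[g]] += factors[si]
    mean = base_mean[:, None] * 2.0**log2_shift
    counts = _nb_sample(rng, mean, dispersion, mean.shape)
    samples = [f"{dataset_id}_T{k:03d}" for k in range(n_samples)]
    values = pd.DataFrame(counts, index=genes, columns=samples)
    ann = pd.DataFrame(
        {"cell": "bulk", "condition": "tumor", "batch": dataset_id, "group": "tumor"},
        index=pd.Index(samples, name="sample"),
    )
    study = GeneExpressionStudy(dataset_id=dataset_id, values=values,
                                scale_tag="count", sample_annotations=ann)
    factor_frame = pd.DataFrame(factors, index=signal_subpathways, columns=samples)
    return study, factor_frame


def generate_drug_screen(
    n_drugs: int,
    n_lines: int,
    genes: Sequence[str],
    collection: SubpathwayCollection,
    drug_drivers: Mapping[str, str],
    effect: float = 2.0,
    noise_sd: float = 0.5,
    seed: int = 0,
) -> DrugScreen:
    """Multi-omic drug screen with planted expression-driven IC50 values.

    For a driven drug, log IC50 = 1 + effect * (mean expression of its driver
    subpathway's members in that line) + N(0, noise_sd); other drugs are pure
    noise. Driver-subpathway members share a per-line latent factor so they
    individually separate high- from low-IC50 lines. Methylation is
    logit-normal, copy number integer in {-2..2}; both are noise layers here.
    """
    if n_lines < 4:
        raise InvalidArgumentError("n_lines must be >= 4 for a median split")
    for drug, sid in drug_drivers.items():
        if sid not in collection:
            raise InvalidArgumentError(f"driver subpathway {sid!r} for {drug!r} not in collection")
    rng = np.random.default_rng(seed)
    genes = list(genes)
    gene_pos = {g: i for i, g in enumerate(genes)}
    lines = [f"L{i:03d}" for i in range(n_lines)]
    drugs = [f"D{i:03d}" for i in range(n_drugs)]
    unknown_drugs = set(drug_drivers) - set(drugs)
    if unknown_drugs:
        raise InvalidArgumentError(f"driver map names unknown drugs: {sorted(unknown_drugs)}")

    expr = rng.normal(0, 1, size=(len(genes), n_lines))
    driver_sids = sorted(set(drug_drivers.values()))
    factors = {sid: rng.normal(0, 1, size=n_lines) for sid in driver_sids}
    for sid in driver_sids:
        for g in collection[sid].members:
            if g in gene_pos:
                expr[gene_pos[g]] += factors[sid]
    expression = pd.DataFrame(expr, index=genes, columns=lines)

    methylation = pd.DataFrame(
        expit(rng.normal(0, 1, size=(len(genes), n_lines))), index=genes, columns=lines
    )
    cnv = pd.DataFrame(
        rng.choice([-2, -1, 0, 1, 2], p=[0.05, 0.2, 0.5, 0.2, 0.05],
                   size=(len(genes), n_lines)),
        index=genes, columns=lines,
    )

    log_ic50 = np.empty((n_drugs, n_lines))
    for di, drug in enumerate(drugs):
        if drug in drug_drivers:
            sid = drug_drivers[drug]
            members = [g for g in collection[sid].members if g in gene_pos]
            driver_mean = expression.loc[members].mean(axis=0).to_numpy()
            log_ic50[di] = 1.0 + effect * driver_mean + rng.normal(0, noise_sd, n_lines)
        else:
            log_ic50[di] = 1.0 + rng.normal(0, 1.0, n_lines)
    ic50 = pd.DataFrame(np.exp(log_ic50), index=drugs, columns=lines)
    return DrugScreen(ic50=ic50, expression=expression,
                      methylation=methylation, cnv=cnv)


# ---------------------------------------------------------------------------
# full simulation bundle

DEFAULT_SIMULATION = {
    "n_genes": 1200,
    "attach": 2,
    "evidence_rate": 0.85,
    "n_subpathways": 150,
    "size_range": [6, 30],
    "overlap_fraction": 0.1,
    "n_signal_subpathways": 5,
    "coefficient_magnitude": 1.0,
    "micmac_datasets": 2,
    "micn_datasets": 3,
    "n_per_group": 10,
    "effect_log2fc": 2.0,
    "dispersion": 0.1,
    "planted_counts": {"MicT/MacT": [55, 36], "MicT/MicN": [59, 5]},
    "train_samples": 100,
    "test_samples": 80,
    "factor_sd": 1.0,
    "baseline_hazard": 0.1,
    "censor_rate": 0.3,
    "n_drugs": 20,
    "n_lines": 40,
    "n_driven_drugs": 8,
    "drug_effect": 2.0,
    "drug_noise_sd": 0.5,
}


@dataclass
class SimulationBundle:
    """Everything one simulation run produced, plus its ground truth."""

    network: InteractionNetwork
    collection: SubpathwayCollection
    studies: dict[str, GeneExpressionStudy]
    train_study: GeneExpressionStudy
    test_study: GeneExpressionStudy
    train_cohort: SurvivalCohort
    test_cohort: SurvivalCohort
    screen: DrugScreen
    truth: SyntheticTruth


def simulate_all(params: Mapping | None = None, seed: int = 0) -> SimulationBundle:
    """Generate a coherent full-pipeline input set under one seed.

    Planted DE genes are drawn partly from the signal subpathways' members, so
    network propagation from the consensus seeds scores those subpathways
    highly; the survival cohorts' hazards follow the true coefficients over
    the signal subpathways' ssGSEA activities; driven drugs' IC50 follows the
    signal subpathways' expression.
    """
    cfg = dict(DEFAULT_SIMULATION)
    if params:
        cfg.update(params)
    rng = np.random.default_rng(seed)

    network = generate_network(cfg["n_genes"], cfg["attach"], cfg["evidence_rate"],
                               seed=int(rng.integers(2**31)))
    collection = generate_subpathways(
        cfg["n_subpathways"], tuple(cfg["size_range"]), network,
        seed=int(rng.integers(2**31)), overlap_fraction=cfg["overlap_fraction"],
    )
    genes = network.genes

    signal = list(rng.choice(collection.ids(), size=cfg["n_signal_subpathways"],
                             replace=False))
    coef = {}
    for i, sid in enumerate(signal):
        coef[sid] = cfg["coefficient_magnitude"] * (1 if i % 2 == 0 else -1)

    planted: dict[str, dict[str, str]] = {}
    signal_members = sorted(set().union(*(collection[s].members for s in signal)))
    other_genes = sorted(set(genes) - set(signal_members))
    for group, (n_up, n_down) in cfg["planted_counts"].items():
        plan: dict[str, str] = {}
        from_signal = list(rng.choice(signal_members,
                                      size=min(n_up, len(signal_members)),
                                      replace=False))
        for g in from_signal:
            plan[g] = "up"
        pool = [g for g in other_genes if g not in plan]
        fill = list(rng.choice(pool, size=max(0, n_up - len(from_signal)) + n_down,
                               replace=False))
        for g in fill[: max(0, n_up - len(from_signal))]:
            plan[g] = "up"
        for g in fill[max(0, n_up - len(from_signal)):]:
            plan[g] = "down"
        planted[group] = plan

    truth = SyntheticTruth(
        planted_de_genes=planted,
        planted_subpathways=set(signal),
        true_coefficients=coef,
        drug_drivers={},
    )

    studies: dict[str, GeneExpressionStudy] = {}
    for i in range(cfg["micmac_datasets"]):
        sid = f"SIM_MM{i + 1}"
        studies[sid] = generate_study(
            sid, {"MicT": cfg["n_per_group"], "MacT": cfg["n_per_group"]},
            truth, cfg["effect_log2fc"], cfg["dispersion"],
            seed=int(rng.integers(2**31)), genes=genes,
        )
    for i in range(cfg["micn_datasets"]):
        sid = f"SIM_MN{i + 1}"
        studies[sid] = generate_study(
            sid, {"MicT": cfg["n_per_group"], "MicN": cfg["n_per_group"]},
            truth, cfg["effect_log2fc"], cfg["dispersion"],
            seed=int(rng.integers(2**31)), genes=genes,
        )

    from .enrichment import ssgsea_scores

    train_study, _ = generate_tumor_study(
        "SIM_TRAIN", cfg["train_samples"], genes, collection, signal,
        cfg["factor_sd"], cfg["dispersion"], seed=int(rng.integers(2**31)),
    )
    test_study, _ = generate_tumor_study(
        "SIM_TEST", cfg["test_samples"], genes, collection, signal,
        cfg["factor_sd"], cfg["dispersion"], seed=int(rng.integers(2**31)),
    )
    train_activity = ssgsea_scores(train_study, collection)
    test_activity = ssgsea_scores(test_study, collection)
    # activities are standardized before entering the hazard so the stated
    # coefficient magnitudes act on a unit scale
    def _std(frame):
        arr = frame.to_numpy()
        return pd.DataFrame(
            (arr - arr.mean(axis=1, keepdims=True)) / arr.std(axis=1, keepdims=True),
            index=frame.index, columns=frame.columns,
        )

    train_cohort = generate_survival(
        _std(train_activity.values), coef, cfg["baseline_hazard"],
        cfg["censor_rate"], seed=int(rng.integers(2**31)),
    )
    test_cohort = generate_survival(
        _std(test_activity.values), coef, cfg["baseline_hazard"],
        cfg["censor_rate"], seed=int(rng.integers(2**31)),
    )

    drugs = [f"D{i:03d}" for i in range(cfg["n_drugs"])]
    driven = list(rng.choice(drugs, size=cfg["n_driven_drugs"], replace=False))
    drivers = {d: signal[i % len(signal)] for i, d in enumerate(driven)}
    truth.drug_drivers = drivers
    screen = generate_drug_screen(
        cfg["n_drugs"], cfg["n_lines"], genes, collection, drivers,
        effect=cfg["drug_effect"], noise_sd=cfg["drug_noise_sd"],
        seed=int(rng.integers(2**31)),
    )
    return SimulationBundle(
        network=network, collection=collection, studies=studies,
        train_study=train_study, test_study=test_study,
        train_cohort=train_cohort, test_cohort=test_cohort,
        screen=screen, truth=truth,
    )
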