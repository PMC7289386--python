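"""Synthetic data with the statistical structure the pipeline assumes.

Expression is generated from a sparse linear-Gaussian structural equation
model (SEM) over a random DAG — exactly the family in which the Fisher-z
partial-correlation test is exact, so structure-recovery performance measures
the learner, not model misfit.  On top of the expression model the generator
emulates the cohort features the analysis consumes:

* left-censored, intensity-dependent missingness (label-free MS dropouts);
* three tumour-subtype groups in the cohort's 50/21/25 proportions, with a
  mean shift on a designated target set of proteins;
* exponential survival whose hazard is proportional to
  ``exp(log_hr * activity)`` of the target set, with independent exponential
  censoring tuned to a target censoring fraction.

The default preset (p=60 proteins, n=96 samples) keeps test runs fast; a
paper-scale preset (p=1095) exists for benchmarking.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import networkx as nx
import numpy as np
import pandas as pd

from .annotation import ANNOTATION_COLUMNS, AnnotationTable
from .group_stats import ClinicalTable
from .preprocess import ExpressionMatrix

COHORT_PROPORTIONS = {"ER-true": 50 / 96, "TN-like": 21 / 96, "TNBC": 25 / 96}

#: sample-type grouping used by the quantifiability filter (ER+ pools the
#: receptor-positive subtypes, mirroring how detection groups are formed)
SAMPLE_TYPE_OF_SUBTYPE = {"ER-true": "ER+", "TN-like": "ER+", "TNBC": "TNBC"}

TARGET_TERM = ("GO:SYN0001", "Extracellular matrix")


@dataclass
class SyntheticTruth:
    """Ground truth of one synthetic cohort."""

    dag: nx.DiGraph
    weights: dict[tuple[str, str], float]
    noise_sd: dict[str, float]
    subtype_effects: dict[tuple[str, str], float]  # (subtype, node) -> shift
    target_nodes: tuple[str, ...]
    baseline_hazard: float = 0.02
    log_hr: float = 1.0
    censoring_rate: float = 0.25
    seed: int = 0

    def __post_init__(self) -> None:
        if not nx.is_directed_acyclic_graph(self.dag):
            raise ValueError("truth graph must be acyclic")
        if not (0.0 <= self.censoring_rate < 1.0):
            raise ValueError("censoring_rate must be in [0, 1)")


def generate_random_dag(
    p: int, edge_prob: float, seed: int = 0, prefix: str = "P"
) -> nx.DiGraph:
    """Random DAG: lower-triangular Bernoulli adjacency under a random node
    permutation, hence guaranteed acyclic; expected edge count
    edge_prob * p * (p-1) / 2."""
    if not (0.0 <= edge_prob <= 1.0):
        raise ValueError("edge_prob must be in [0, 1]")
    rng = np.random.default_rng(seed)
    names = [f"{prefix}{i:04d}" for i in range(p)]
    perm = rng.permutation(p)
    dag = nx.DiGraph()
    dag.add_nodes_from(names)
    mask = np.tril(rng.random((p, p)) < edge_prob, k=-1)
    for i, j in zip(*np.nonzero(mask)):
        dag.add_edge(names[perm[j]], names[perm[i]])  # earlier -> later
    return dag


def make_truth(
    p: int = 60,
    edge_prob: float = 0.05,
    seed: int = 0,
    weight_range: tuple[float, float] = (0.5, 1.5),
    noise_sd: float = 1.0,
    target_size: int = 8,
    subtype_shift: float = 1.0,
    baseline_hazard: float = 0.02,
    log_hr: float = 1.0,
    censoring_rate: float = 0.25,
) -> SyntheticTruth:
    """Assemble a full synthetic truth around a random sparse DAG.

    Edge weights are uniform in +-[weight_range] with random sign.  The
    target set (the nodes whose mean activity drives subtype shifts and the
    hazard) is drawn from the largest connected region of the DAG so it
    behaves like a network component.
    """
    rng = np.random.default_rng(seed)
    dag = generate_random_dag(p, edge_prob, seed)
    lo, hi = weight_range
    weights = {
        e: float(rng.uniform(lo, hi) * rng.choice([-1.0, 1.0])) for e in sorted(dag.edges)
    }
    comps = sorted(
        nx.connected_components(dag.to_undirected()), key=lambda c: (-len(c), min(c))
    )
    if comps:
        # breadth-first from the largest region's smallest node, so the
        # target is a *connected* subgraph (a coherent network component)
        ug = dag.to_undirected()
        target_set, frontier = set(), [min(comps[0])]
        while frontier and len(target_set) < target_size:
            v = frontier.pop(0)
            if v in target_set:
                continue
            target_set.add(v)
            frontier.extend(sorted(set(ug.neighbors(v)) - target_set))
        target = tuple(sorted(target_set))
        # the target emulates a co-regulated functional module: members rise
        # and fall together, so a mean activity is a meaningful summary —
        # force positive coupling on its internal edges
        for u, v in dag.edges:
            if u in target_set and v in target_set:
                weights[(u, v)] = abs(weights[(u, v)])
    else:
        target = ()
    effects: dict[tuple[str, str], float] = {}
    for v in target:
        effects[("TN-like", v)] = subtype_shift
        effects[("TNBC", v)] = 0.5 * subtype_shift
    return SyntheticTruth(
        dag=dag,
        weights=weights,
        noise_sd={v: noise_sd for v in dag.nodes},
        subtype_effects=effects,
        target_nodes=target,
        baseline_hazard=baseline_hazard,
        log_hr=log_hr,
        censoring_rate=censoring_rate,
        seed=seed,
    )


def implied_covariance(truth: SyntheticTruth) -> tuple[list[str], np.ndarray]:
    """Model-implied covariance (I - B)^-1 D (I - B)^-T of the SEM."""
    nodes = sorted(truth.dag.nodes)
    idx = {v: k for k, v in enumerate(nodes)}
    p = len(nodes)
    B = np.zeros((p, p))
    for (u, v), w in truth.weights.items():
        B[idx[v], idx[u]] = w
    D = np.diag([truth.noise_sd[v] ** 2 for v in nodes])
    inv = np.linalg.inv(np.eye(p) - B)
    return nodes, inv @ D @ inv.T


def draw_subtypes(
    n: int,
    seed: int = 0,
    proportions: dict[str, float] = COHORT_PROPORTIONS,
) -> pd.Series:
    """Subtype labels for n samples in (approximately) cohort proportions."""
    rng = np.random.default_rng(seed)
    labels = sorted(proportions)
    probs = np.array([proportions[k] for k in labels], float)
    probs = probs / probs.sum()
    draw = rng.choice(labels, size=n, p=probs)
    return pd.Series(draw, index=[f"S{i:03d}" for i in range(n)])


def sample_sem(
    truth: SyntheticTruth,
    n: int,
    seed: int = 0,
    subtypes: pd.Series | None = None,
    standardize: bool = True,
) -> ExpressionMatrix:
    """Draw n samples from the linear-Gaussian SEM (topological order).

    Subtype mean shifts (if any, and if ``subtypes`` is given) enter as
    offsets on the exogenous noise of the shifted nodes, so they propagate
    through the graph like any other source of variation.  Rows are
    z-score standardised by default (stage 'zscored'); with
    ``standardize=False`` the raw SEM values are returned at stage 'imputed'
    (complete, unscaled).
    """
    if n < 4:
        raise ValueError("need n >= 4 samples")
    rng = np.random.default_rng(seed)
    nodes = sorted(truth.dag.nodes)
    sample_ids = (
        list(subtypes.index) if subtypes is not None else [f"S{i:03d}" for i in range(n)]
    )
    if subtypes is not None and len(subtypes) != n:
        raise ValueError("subtypes length must equal n")
    X = pd.DataFrame(0.0, index=nodes, columns=sample_ids)
    eps = {
        v: rng.normal(0.0, truth.noise_sd[v], size=n) for v in nodes
    }
    if subtypes is not None:
        for (subtype, v), shift in truth.subtype_effects.items():
            eps[v] = eps[v] + shift * (subtypes.to_numpy() == subtype)
    for v in nx.topological_sort(truth.dag):
        total = eps[v].copy()
        for u in truth.dag.predecessors(v):
            total = total + truth.weights[(u, v)] * X.loc[u].to_numpy()
        X.loc[v] = total
    if not standardize:
        return ExpressionMatrix(X, stage="imputed")
    vals = X.to_numpy()
    z = (vals - vals.mean(axis=1, keepdims=True)) / vals.std(axis=1, keepdims=True)
    return ExpressionMatrix(
        pd.DataFrame(z, index=X.index, columns=X.columns), stage="zscored"
    )


def inject_missingness(
    matrix: ExpressionMatrix,
    rate: float,
    intensity_dependence: float = 1.0,
    seed: int = 0,
) -> ExpressionMatrix:
    """Mask entries as missing with (optionally) intensity-dependent odds.

    Missingness probability is logistic in the negative standardised value:
    low-abundance entries drop out preferentially when
    ``intensity_dependence > 0`` (left censoring); 0 gives missing completely
    at random.  The intercept is calibrated by bisection so the overall
    missing fraction matches ``rate``.
    """
    if not (0.0 <= rate < 1.0):
        raise ValueError("rate must be in [0, 1)")
    if rate == 0.0:
        return matrix.copy()
    rng = np.random.default_rng(seed)
    vals = matrix.data.to_numpy(float)
    std = (vals - np.nanmean(vals)) / np.nanstd(vals)
    d = float(intensity_dependence)

    def mean_prob(c: float) -> float:
        return float(np.nanmean(1.0 / (1.0 + np.exp(-(c - d * std)))))

    lo, hi = -30.0, 30.0
    for _ in range(80):
        mid = 0.5 * (lo + hi)
        if mean_prob(mid) < rate:
            lo = mid
        else:
            hi = mid
    c = 0.5 * (lo + hi)
    prob = 1.0 / (1.0 + np.exp(-(c - d * std)))
    mask = rng.random(vals.shape) < prob
    out = matrix.data.mask(pd.DataFrame(mask, index=matrix.data.index,
                                        columns=matrix.data.columns))
    return ExpressionMatrix(out, stage=matrix.stage if matrix.stage in ("raw", "log2") else "raw")


def target_activity(matrix: ExpressionMatrix, truth: SyntheticTruth) -> pd.Series:
    """Mean z-score of the truth's target nodes, per sample."""
    return matrix.data.loc[list(truth.target_nodes)].mean(axis=0)


def generate_clinical(
    truth: SyntheticTruth,
    activities: pd.Series,
    seed: int = 0,
    subtypes: pd.Series | None = None,
) -> ClinicalTable:
    """Survival data with hazard tied to the target-component activity.

    Event times are exponential with per-sample rate
    ``baseline_hazard * exp(log_hr * activity)``; censoring times are an
    independent exponential whose rate is tuned (bisection) so the expected
    censoring fraction matches ``truth.censoring_rate``.
    """
    rng = np.random.default_rng(seed)
    act = activities.to_numpy(float)
    n = len(act)
    if subtypes is None:
        subtypes = pd.Series(
            draw_subtypes(n, seed=seed + 1).to_numpy(), index=activities.index
        )
    lam = truth.baseline_hazard * np.exp(truth.log_hr * act)
    T = rng.exponential(1.0 / lam)
    if truth.censoring_rate == 0.0:
        times, events = T, np.ones(n, bool)
    else:
        target = truth.censoring_rate

        def frac_censored(c: float) -> float:
            return float(np.mean(c / (c + lam)))

        lo, hi = 1e-12, 1e6
        for _ in range(200):
            mid = np.sqrt(lo * hi)
            if frac_censored(mid) < target:
                lo = mid
            else:
                hi = mid
        c = np.sqrt(lo * hi)
        C = rng.exponential(1.0 / c, size=n)
        events = T <= C
        times = np.minimum(T, C)
    df = pd.DataFrame(
        {
            "subtype": subtypes.loc[activities.index].to_numpy(),
            "time": times,
            "event": events,
        },
        index=activities.index,
    )
    df.index.name = "sample_id"
    return ClinicalTable(df)


# ---------------------------------------------------------------------------
# full-cohort bundle (what the `simulate` CLI writes)
# ---------------------------------------------------------------------------

@dataclass
class SyntheticCohort:
    truth: SyntheticTruth
    raw: ExpressionMatrix            # intensity scale, with missing values
    zscored: ExpressionMatrix        # truth-level standardised expression
    peptide_counts: dict[str, int]
    groups: dict[str, str]           # sample -> sample-type label (filter groups)
    subtypes: pd.Series
    clinical: ClinicalTable
    annotation: AnnotationTable


def generate_cohort(
    p: int = 60,
    n: int = 96,
    seed: int = 0,
    edge_prob: float = 0.05,
    missing_rate: float = 0.08,
    intensity_dependence: float = 1.0,
    **truth_kwargs,
) -> SyntheticCohort:
    """End-to-end synthetic cohort exercising every pipeline stage.

    The z-scored SEM draw is mapped back to a raw intensity scale
    (``2 ** (z + per-protein log2 abundance)``), missingness is injected
    there, and peptide counts / sample-type groups / clinical and annotation
    tables are attached so the result feeds the full pipeline from its raw
    entry point.
    """
    ss = np.random.SeedSequence(seed)
    s_truth, s_sub, s_expr, s_miss, s_clin, s_misc = [
        int(c.generate_state(1)[0] % (2**31)) for c in ss.spawn(6)
    ]
    truth = make_truth(p=p, edge_prob=edge_prob, seed=s_truth, **truth_kwargs)
    subtypes = draw_subtypes(n, seed=s_sub)
    z = sample_sem(truth, n, seed=s_expr, subtypes=subtypes)
    rng = np.random.default_rng(s_misc)
    base = rng.uniform(18.0, 28.0, size=z.n_proteins)  # per-protein log2 abundance
    log2_vals = z.data.to_numpy() + base[:, None]
    log2_m = ExpressionMatrix(
        pd.DataFrame(log2_vals, index=z.data.index, columns=z.data.columns),
        stage="log2",
    )
    log2_missing = inject_missingness(
        log2_m, missing_rate, intensity_dependence, seed=s_miss
    )
    raw = ExpressionMatrix(2.0 ** log2_missing.data, stage="raw")
    peptide_counts = {
        v: int(k) for v, k in zip(z.protein_ids, rng.integers(1, 13, size=z.n_proteins))
    }
    groups = {s: SAMPLE_TYPE_OF_SUBTYPE[t] for s, t in subtypes.items()}
    clinical = generate_clinical(
        truth, target_activity(z, truth), seed=s_clin, subtypes=subtypes
    )
    annotation = _synthetic_annotation(truth, rng)
    return SyntheticCohort(
        truth=truth,
        raw=raw,
        zscored=z,
        peptide_counts=peptide_counts,
        groups=groups,
        subtypes=subtypes,
        clinical=clinical,
        annotation=annotation,
    )


def _synthetic_annotation(truth: SyntheticTruth, rng) -> AnnotationTable:
    """Annotation table: target nodes carry the target term; the rest draw
    from a small pool of filler terms."""
    filler = [
        ("GO:SYN0002", "Mitochondrion"),
        ("GO:SYN0003", "RNA binding"),
        ("GO:SYN0004", "Cytoskeleton"),
        ("GO:SYN0005", "Extracellular exosome"),
    ]
    rows = []
    for v in truth.target_nodes:
        rows.append([v, v, *TARGET_TERM, "GO"])
    for v in sorted(truth.dag.nodes):
        if v in truth.target_nodes:
            continue
        tid, tlabel = filler[int(rng.integers(len(filler)))]
        rows.append([v, v, tid, tlabel, "GO"])
    df = pd.DataFrame(rows, columns=ANNOTATION_COLUMNS)
    return AnnotationTable(df, background=max(20_000, len(truth.dag.nodes)))


def truth_to_tsv(truth: SyntheticTruth, path) -> None:
    """Serialise the generating DAG as a weighted edge-list TSV."""
    rows = [
        {"source": u, "target": v, "weight": w}
        for (u, v), w in sorted(truth.weights.items())
    ]
    pd.DataFrame(rows, columns=["source", "target", "weight"]).to_csv(
        path, sep="\t", index=False
    )
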