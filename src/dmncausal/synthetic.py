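"""Synthetic resting-state cohorts from stable VAR processes.

Subjects are drawn from a vector autoregression over the 8 DMN nodes with a
known, hub-centric directed coupling structure, so that every downstream
stage (Granger fitting, surrogate testing, graph metrics, classification)
can be validated against exact ground truth.  A "control" coupling mimics a
healthy cohort in which the hubs (PCC, MPFC, bilateral IPC) interact with
every other node and the PCC only receives influence; an "attenuated"
variant scales down all couplings incident to MPFC/lIPC/rIPC — while
preserving those incident to PCC — emulating the hub-communication loss
seen in Alzheimer's disease.

The cross-coupling graph of the default specs is acyclic (all feedback sits
in the per-node autoregressive terms), so the process is stationary for any
coupling strength and the ground-truth Granger structure is unambiguous.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np

from .network import CausalGraph
from .timeseries import DEFAULT_HUB_LABELS, DEFAULT_NODE_LABELS, TimeSeriesMatrix

#: Default self-autoregressive coefficients per node, by lag.
DEFAULT_SELF_COEFFICIENTS: tuple[float, ...] = (0.3, 0.1)

#: Default directed coupling strength (edge coefficient).
DEFAULT_COUPLING = 0.4

#: Default attenuation factor for the AD-like cohort.
DEFAULT_ATTENUATION = 0.4

_BURN_IN = 200
_MAX_JITTER_RETRIES = 20


@dataclass(frozen=True)
class Edge:
    """One directed coupling: ``target_t += coefficient * source_{t-lag}``."""

    source: str
    target: str
    lag: int
    coefficient: float


@dataclass(frozen=True)
class CouplingSpec:
    """Ground-truth VAR coupling structure for one group.

    Parameters
    ----------
    node_labels, hub_labels : tuple of str
        Region names and the hub subset.
    edges : tuple of Edge
        Directed cross-couplings; lags must lie in 1..order.
    self_coefficients : mapping label -> tuple of float
        Per-node autoregressive coefficients, one per lag starting at 1.
    noise_sd : mapping label -> float
        Innovation standard deviation per node.
    """

    node_labels: tuple[str, ...] = DEFAULT_NODE_LABELS
    hub_labels: tuple[str, ...] = DEFAULT_HUB_LABELS
    edges: tuple[Edge, ...] = ()
    self_coefficients: Mapping[str, tuple[float, ...]] = field(default_factory=dict)
    noise_sd: Mapping[str, float] = field(default_factory=dict)

    def __post_init__(self) -> None:
        object.__setattr__(self, "node_labels", tuple(self.node_labels))
        object.__setattr__(self, "hub_labels", tuple(self.hub_labels))
        object.__setattr__(self, "edges", tuple(self.edges))
        nodes = set(self.node_labels)
        if not set(self.hub_labels) <= nodes:
            raise ValueError("hub_labels must be a subset of node_labels")
        for e in self.edges:
            if e.source not in nodes or e.target not in nodes:
                raise ValueError(f"edge {e.source}->{e.target} outside node_labels")
            if e.source == e.target:
                raise ValueError("self couplings belong in self_coefficients")
            if e.lag < 1:
                raise ValueError(f"edge lag {e.lag} must be >= 1")
        for label in self.self_coefficients:
            if label not in nodes:
                raise ValueError(f"self coefficient for unknown node {label!r}")
        for label in self.noise_sd:
            if label not in nodes:
                raise ValueError(f"noise sd for unknown node {label!r}")

    @property
    def order(self) -> int:
        """Maximum lag appearing in cross or self terms (VAR order)."""
        lags = [e.lag for e in self.edges]
        lags += [len(c) for c in self.self_coefficients.values()]
        return max(lags, default=1)

    def sd_of(self, label: str) -> float:
        return float(self.noise_sd.get(label, 1.0))

    def coefficient_matrices(self) -> np.ndarray:
        """Stacked lag matrices A, shape (order, R, R), row = target."""
        p = self.order
        r = len(self.node_labels)
        idx = {n: i for i, n in enumerate(self.node_labels)}
        a = np.zeros((p, r, r))
        for label, coeffs in self.self_coefficients.items():
            for lag, c in enumerate(coeffs, start=1):
                a[lag - 1, idx[label], idx[label]] += c
        for e in self.edges:
            a[e.lag - 1, idx[e.target], idx[e.source]] += e.coefficient
        return a

    def companion_matrix(self) -> np.ndarray:
        a = self.coefficient_matrices()
        p, r, _ = a.shape
        comp = np.zeros((p * r, p * r))
        comp[:r] = np.concatenate(list(a), axis=1)
        if p > 1:
            comp[r:, : r * (p - 1)] = np.eye(r * (p - 1))
        return comp

    def spectral_radius(self) -> float:
        return float(np.max(np.abs(np.linalg.eigvals(self.companion_matrix()))))

    def is_stationary(self) -> bool:
        return self.spectral_radius() < 1.0

    def ground_truth_graph(self) -> CausalGraph:
        """Binary graph of nonzero directed couplings."""
        edges = frozenset(
            (e.source, e.target) for e in self.edges if e.coefficient != 0.0
        )
        return CausalGraph(self.node_labels, self.hub_labels, edges)

    def to_json_dict(self) -> dict:
        return {
            "node_labels": list(self.node_labels),
            "hub_labels": list(self.hub_labels),
            "edges": [
                [e.source, e.target, e.lag, e.coefficient] for e in self.edges
            ],
            "self_coefficients": {
                k: list(v) for k, v in self.self_coefficients.items()
            },
            "noise_sd": dict(self.noise_sd),
        }

    @classmethod
    def from_json_dict(cls, d: Mapping) -> "CouplingSpec":
        return cls(
            node_labels=tuple(d["node_labels"]),
            hub_labels=tuple(d["hub_labels"]),
            edges=tuple(Edge(s, t, int(l), float(c)) for s, t, l, c in d["edges"]),
            self_coefficients={
                k: tuple(v) for k, v in d["self_coefficients"].items()
            },
            noise_sd=dict(d["noise_sd"]),
        )


@dataclass(frozen=True)
class CohortSpec:
    """Recipe for one simulated cohort.

    ``between_subject_jitter`` is the relative standard deviation of the
    multiplicative Gaussian perturbation applied independently to each edge
    coefficient per subject (truncated so the perturbed coefficient keeps
    its sign).  ``n_timepoints`` defaults to 295 = 300 acquisitions minus
    the 5 discarded initial volumes at TR = 2 s.
    """

    coupling: CouplingSpec
    n_subjects: int = 16
    n_timepoints: int = 295
    tr_seconds: float = 2.0
    between_subject_jitter: float = 0.1
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_subjects < 1:
            raise ValueError("n_subjects must be >= 1")
        if self.n_timepoints <= 10 * self.coupling.order:
            raise ValueError(
                f"n_timepoints must exceed 10 x order = {10 * self.coupling.order}"
            )
        if self.between_subject_jitter < 0:
            raise ValueError("jitter must be >= 0")

    def to_json_dict(self) -> dict:
        return {
            "coupling": self.coupling.to_json_dict(),
            "n_subjects": self.n_subjects,
            "n_timepoints": self.n_timepoints,
            "tr_seconds": self.tr_seconds,
            "between_subject_jitter": self.between_subject_jitter,
            "seed": self.seed,
        }

    @classmethod
    def from_json_dict(cls, d: Mapping) -> "CohortSpec":
        return cls(
            coupling=CouplingSpec.from_json_dict(d["coupling"]),
            n_subjects=int(d["n_subjects"]),
            n_timepoints=int(d["n_timepoints"]),
            tr_seconds=float(d["tr_seconds"]),
            between_subject_jitter=float(d["between_subject_jitter"]),
            seed=int(d["seed"]),
        )


def make_default_coupling(
    group: str = "control",
    attenuation_factor: float = DEFAULT_ATTENUATION,
    coupling: float = DEFAULT_COUPLING,
    node_labels: Sequence[str] = DEFAULT_NODE_LABELS,
    hub_labels: Sequence[str] = DEFAULT_HUB_LABELS,
    edge_lag: int = 1,
    sink_lag: int = 3,
) -> CouplingSpec:
    """Hub-centric coupling spec for a control or AD-like ("attenuated") group.

    Control structure (directed, acyclic):

    - every hub-hub and hub-non-hub pair carries exactly one directed
      coupling; non-hub pairs carry none;
    - PCC only receives: all seven other nodes send an edge into PCC and
      PCC sends none;
    - non-hub nodes are exogenous sources (pure autoregressions) driving
      every non-PCC hub, and the hubs MPFC, lIPC, rIPC additionally drive
      each other in a fixed hierarchy.

    Making the non-hubs exogenous keeps the bivariate ground truth exact:
    co-driven nodes share no upstream signal, so uncoupled ordered pairs
    carry (asymptotically) zero bivariate Granger causality, which a
    pairwise analysis can verify.

    The attenuated variant multiplies every coupling incident to MPFC,
    lIPC or rIPC by ``attenuation_factor``, except couplings incident to
    PCC, which are left intact (in AD the PCC keeps its causal relations
    with all other nodes while MPFC/IPC communication degrades).

    Cross couplings act at a common lag (``edge_lag``, default 1), except
    the couplings converging on the PCC sink, which act at ``sink_lag``
    (default 3, i.e. a 6 s convergence delay at TR = 2 s); hub nodes carry
    self terms (0.3, 0.1) at lags 1-2 while the exogenous non-hub sources
    are white.  These choices are deliberate: with a common coupling
    delay, serially uncorrelated sources, and a sink whose aggregated past
    holds only stale copies of the other nodes' driver states, each node's
    own past shields the information an indirectly connected node could
    contribute — so the *bivariate* Granger ground truth coincides with
    the structural edge set and recovery tests are exact.  Heterogeneous
    upstream lags, autocorrelated shared sources, or a fresh sink (which
    would act as an extra noisy sensor of every node's recent drivers)
    all make structurally uncoupled ordered pairs genuinely
    Granger-causal in the bivariate sense.
    """
    if group not in ("control", "attenuated"):
        raise ValueError(f"unknown group {group!r}")
    if not 0.0 <= attenuation_factor <= 1.0:
        raise ValueError("attenuation_factor must lie in [0, 1]")
    node_labels = tuple(node_labels)
    hub_labels = tuple(hub_labels)
    pcc = hub_labels[0]  # sink hub: only receives
    other_hubs = [h for h in hub_labels if h != pcc]
    non_hubs = [n for n in node_labels if n not in hub_labels]

    pairs: list[tuple[str, str]] = []
    # hierarchy among the driving hubs (earlier drives later)
    for i, s in enumerate(other_hubs):
        for t in other_hubs[i + 1 :]:
            pairs.append((s, t))
    # each non-hub source feeds each non-PCC hub
    for s in non_hubs:
        for t in other_hubs:
            pairs.append((s, t))
    # everything sends into the sink hub
    for s in other_hubs + non_hubs:
        pairs.append((s, pcc))

    edges = []
    for s, t in pairs:
        c = coupling
        if group == "attenuated" and pcc not in (s, t):
            # MPFC/lIPC/rIPC-incident couplings attenuate; PCC-incident
            # couplings (including those sent by other hubs) are preserved
            if s in hub_labels or t in hub_labels:
                c = coupling * attenuation_factor
        edges.append(Edge(s, t, lag=sink_lag if t == pcc else edge_lag, coefficient=c))

    return CouplingSpec(
        node_labels=node_labels,
        hub_labels=hub_labels,
        edges=tuple(edges),
        self_coefficients={n: DEFAULT_SELF_COEFFICIENTS for n in hub_labels},
        noise_sd={n: 1.0 for n in node_labels},
    )


def double_gamma_hrf(tr_seconds: float = 2.0, duration_s: float = 32.0) -> np.ndarray:
    """Canonical double-gamma hemodynamic response sampled at the TR.

    Peak at ~6 s with a ~16 s undershoot of 1/6 relative amplitude,
    normalized to unit sum.
    """
    import scipy.stats

    t = np.arange(0.0, duration_s + tr_seconds / 2, tr_seconds)
    h = scipy.stats.gamma.pdf(t, 6) - scipy.stats.gamma.pdf(t, 16) / 6.0
    return h / h.sum()


def simulate_subject(
    coupling: CouplingSpec,
    n_timepoints: int = 295,
    seed: int | np.random.SeedSequence = 0,
    tr_seconds: float = 2.0,
    burn_in: int = _BURN_IN,
    hrf_convolve: bool = False,
) -> TimeSeriesMatrix:
    """Simulate one subject by iterating the VAR recursion.

    Gaussian innovations; a burn-in of ``burn_in`` (>= 200) steps is
    discarded so the recorded segment is free of initial-condition
    transients.  Identical (coupling, n_timepoints, seed) yields
    bit-identical output.

    ``hrf_convolve`` optionally smears the neuronal-level VAR output with
    the canonical double-gamma hemodynamic response.  It is off by
    default: the causal ground truth is defined at the VAR level, and
    convolution blurs the lag structure the recovery tests rely on.
    """
    radius = coupling.spectral_radius()
    if radius >= 1.0:
        raise ValueError(
            f"coupling is non-stationary: companion spectral radius "
            f"{radius:.4f} >= 1"
        )
    p = coupling.order
    if n_timepoints <= 10 * p:
        raise ValueError(f"n_timepoints must exceed 10 x order = {10 * p}")
    if burn_in < 200:
        raise ValueError("burn_in must be >= 200 steps")
    r = len(coupling.node_labels)
    a = coupling.coefficient_matrices()  # (p, R, R)
    sd = np.array([coupling.sd_of(n) for n in coupling.node_labels])
    rng = np.random.default_rng(seed)
    total = burn_in + n_timepoints
    x = np.zeros((total + p, r))
    innov = rng.normal(0.0, 1.0, size=(total, r)) * sd
    for t in range(p, total + p):
        acc = innov[t - p]
        for lag in range(1, p + 1):
            acc = acc + a[lag - 1] @ x[t - lag]
        x[t] = acc
    values = x[p + burn_in :]
    if hrf_convolve:
        h = double_gamma_hrf(tr_seconds)
        values = np.column_stack(
            [np.convolve(values[:, c], h)[: n_timepoints] for c in range(r)]
        )
    return TimeSeriesMatrix(values, coupling.node_labels, tr_seconds)


def _jitter_coupling(
    coupling: CouplingSpec, jitter: float, rng: np.random.Generator
) -> CouplingSpec:
    """Multiplicative Gaussian jitter on edge coefficients, sign-preserving.

    The factor 1 + jitter*z is truncated below at 0.05 so a nonzero
    coupling never vanishes or flips sign.
    """
    if jitter == 0.0 or not coupling.edges:
        return coupling
    factors = np.maximum(
        1.0 + jitter * rng.normal(size=len(coupling.edges)), 0.05
    )
    edges = tuple(
        replace(e, coefficient=e.coefficient * f)
        for e, f in zip(coupling.edges, factors)
    )
    return replace(coupling, edges=edges)


def simulate_cohort(
    spec: CohortSpec,
) -> tuple[list[TimeSeriesMatrix], list[CausalGraph]]:
    """Simulate a cohort; returns subject matrices and ground-truth graphs.

    The master seed determines every per-subject seed (via seed-sequence
    spawning), so two runs with the same spec are identical.  A jitter draw
    that breaks stationarity is resampled up to a capped retry count.
    """
    master = np.random.SeedSequence(spec.seed)
    subject_seeds = master.spawn(spec.n_subjects)
    matrices: list[TimeSeriesMatrix] = []
    graphs: list[CausalGraph] = []
    for ss in subject_seeds:
        jitter_rng = np.random.default_rng(ss.spawn(1)[0])
        coupling = None
        for _ in range(_MAX_JITTER_RETRIES):
            cand = _jitter_coupling(spec.coupling, spec.between_subject_jitter, jitter_rng)
            if cand.is_stationary():
                coupling = cand
                break
        if coupling is None:
            raise RuntimeError(
                f"could not draw a stationary jittered coupling in "
                f"{_MAX_JITTER_RETRIES} attempts"
            )
        matrices.append(
            simulate_subject(
                coupling, spec.n_timepoints, seed=ss, tr_seconds=spec.tr_seconds
            )
        )
        graphs.append(coupling.ground_truth_graph())
    return matrices, graphs


def write_cohort(
    directory: str | Path,
    spec: CohortSpec,
    matrices: Sequence[TimeSeriesMatrix],
    graphs: Sequence[CausalGraph],
    prefix: str = "subject",
) -> None:
    """Write a cohort as per-subject TSVs plus a JSON sidecar.

    The sidecar records the cohort spec and each subject's ground-truth
    edge set.
    """
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    for i, m in enumerate(matrices):
        m.to_tsv(directory / f"{prefix}_{i:03d}.tsv")
    sidecar = {
        "cohort_spec": spec.to_json_dict(),
        "subjects": [
            {
                "file": f"{prefix}_{i:03d}.tsv",
                "ground_truth_edges": sorted(list(e) for e in g.edges),
            }
            for i, g in enumerate(graphs)
        ],
    }
    (directory / "cohort.json").write_text(json.dumps(sidecar, indent=2))


def read_cohort(
    directory: str | Path,
) -> tuple[CohortSpec, list[TimeSeriesMatrix], list[CausalGraph]]:
    """Read a cohort written by :func:`write_cohort`."""
    directory = Path(directory)
    sidecar = json.loads((directory / "cohort.json").read_text())
    spec = CohortSpec.from_json_dict(sidecar["cohort_spec"])
    matrices, graphs = [], []
    for entry in sidecar["subjects"]:
        matrices.append(
            TimeSeriesMatrix.from_tsv(
                directory / entry["file"], tr_seconds=spec.tr_seconds
            )
        )
        graphs.append(
            CausalGraph(
                spec.coupling.node_labels,
                spec.coupling.hub_labels,
                frozenset((s, t) for s, t in entry["ground_truth_edges"]),
            )
        )
    return spec, matrices, graphs
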