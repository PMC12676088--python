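"""Null-model inference: Z-scores, empirical p-values, network verdicts.

The end-to-end question: is an observed plant-fungus association matrix
more (or less) nested and more (or less) modular than expected from its
degree sequence alone?  The pipeline fits the BiCM, draws a null ensemble
(999 matrices by default), scores every null matrix with the same metrics
as the observed one, and summarizes the deviation as

    z = (observed - null mean) / null SD

with empirical tail probabilities using the add-one Monte-Carlo estimator
(count + 1) / (n_null + 1), ties counted as extreme.  Verdicts at
significance alpha follow the sign convention: a negative NODF z-score
with a small lower-tail p-value means anti-nested; a positive Q z-score
with a small upper-tail p-value means modular.

Null matrices are scored exactly as drawn — empty rows or columns arising
in a sample are not re-pruned (zero fills contribute 0 to NODF and
isolates get singleton modules), so observed and null metrics always
refer to the same layer sizes.
"""

from __future__ import annotations

import dataclasses
import json
import math
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

from .bicm import BiCMFit, fit_bicm, iter_ensemble
from .incidence import BipartiteIncidence
from .metrics import ModulePartition, nodf, optimize_modularity

__all__ = [
    "NullEnsembleResult",
    "NetworkReport",
    "zscore",
    "empirical_pvalue",
    "analyze_network",
    "batch_analyze",
    "summarize_reports",
]

METRIC_NODF = "NODF"
METRIC_Q = "Q"


def zscore(observed: float, null_values: Sequence[float]) -> float:
    """Z-score of ``observed`` against a null sample (sample SD, n-1).

    Zero-variance convention: returns 0 when the observed value equals
    the null mean, otherwise a signed infinity sentinel.
    """
    nulls = np.asarray(null_values, dtype=float)
    if nulls.size < 2:
        raise ValueError("z-score needs at least 2 null values")
    mean = nulls.mean()
    # identical null values: the SD is exactly 0 (np.std can report ~1e-17
    # from mean roundoff, which would produce a meaningless huge z)
    if nulls.max() == nulls.min():
        if observed == nulls[0]:
            return 0.0
        return math.copysign(math.inf, observed - nulls[0])
    sd = nulls.std(ddof=1)
    return float((observed - mean) / sd)


def empirical_pvalue(
    observed: float, null_values: Sequence[float], tail: str = "lower"
) -> float:
    """Add-one empirical p-value, ties counted as extreme.

    ``(count of nulls <= observed [lower] or >= observed [upper]) + 1``
    over ``n_null + 1``; never returns 0.
    """
    nulls = np.asarray(null_values, dtype=float)
    if nulls.size < 1:
        raise ValueError("empirical p-value needs at least 1 null value")
    if tail == "lower":
        count = int((nulls <= observed).sum())
    elif tail == "upper":
        count = int((nulls >= observed).sum())
    else:
        raise ValueError(f"tail must be 'lower' or 'upper', got {tail!r}")
    return (count + 1) / (nulls.size + 1)


@dataclasses.dataclass(frozen=True)
class NullEnsembleResult:
    """Null distribution of one metric with observed value and deviation."""

    metric: str
    observed: float
    null_values: tuple[float, ...]
    null_mean: float
    null_sd: float
    z: float
    p_lower: float
    p_upper: float
    n_null: int
    degenerate: bool

    @classmethod
    def from_null_sample(
        cls, metric: str, observed: float, null_values: Sequence[float]
    ) -> "NullEnsembleResult":
        nulls = np.asarray(null_values, dtype=float)
        z = zscore(observed, nulls)
        degenerate = bool(nulls.max() == nulls.min())
        return cls(
            metric=metric,
            observed=float(observed),
            null_values=tuple(float(v) for v in nulls),
            null_mean=float(nulls.mean()),
            null_sd=0.0 if degenerate else float(nulls.std(ddof=1)),
            z=z,
            p_lower=empirical_pvalue(observed, nulls, "lower"),
            p_upper=empirical_pvalue(observed, nulls, "upper"),
            n_null=int(nulls.size),
            degenerate=degenerate,
        )

    def verdict(self, labels: tuple[str, str], alpha: float = 0.05) -> str:
        """Three-way call: labels = (high-side name, low-side name)."""
        high, low = labels
        if not self.degenerate and self.z > 0 and self.p_upper <= alpha:
            return high
        if not self.degenerate and self.z < 0 and self.p_lower <= alpha:
            return low
        return "indistinguishable"


@dataclasses.dataclass(frozen=True)
class NetworkReport:
    """Full per-network analysis: metrics, null distributions, verdicts."""

    dataset_id: str
    n_rows: int
    n_cols: int
    n_links: int
    results: dict[str, NullEnsembleResult]
    verdicts: dict[str, str]
    observed_partition: ModulePartition | None
    fit_residual: float
    fit_iterations: int
    fit_loglik: float
    fit_degenerate: bool
    n_null: int
    n_restarts: int
    null_restarts: int
    alpha: float
    seed: int

    def to_json(self, indent: int = 2) -> str:
        def encode(obj):
            if dataclasses.is_dataclass(obj) and not isinstance(obj, type):
                return dataclasses.asdict(obj)
            raise TypeError(f"not JSON-serializable: {type(obj)}")

        return json.dumps(dataclasses.asdict(self), default=encode, sort_keys=True, indent=indent)

    @classmethod
    def from_json(cls, text: str) -> "NetworkReport":
        raw = json.loads(text)
        raw["results"] = {
            name: NullEnsembleResult(
                **{**res, "null_values": tuple(res["null_values"])}
            )
            for name, res in raw["results"].items()
        }
        if raw.get("observed_partition") is not None:
            part = raw["observed_partition"]
            raw["observed_partition"] = ModulePartition(
                tuple(part["row_modules"]), tuple(part["col_modules"]),
                part["q"], part["n_modules"],
            )
        return cls(**raw)


def _nodf_or_zero(inc: BipartiteIncidence) -> float:
    return nodf(inc).nodf if inc.n_links > 0 else 0.0


def analyze_network(
    inc: BipartiteIncidence,
    n_null: int = 999,
    n_restarts: int = 20,
    null_restarts: int = 5,
    seed: int = 0,
    alpha: float = 0.05,
    metrics: Sequence[str] = (METRIC_NODF, METRIC_Q),
    dataset_id: str = "network",
    fit: BiCMFit | None = None,
) -> NetworkReport:
    """Run the full null-model analysis on one incidence matrix.

    Fits the BiCM (unless a pre-computed ``fit`` is supplied), draws
    ``n_null`` Bernoulli samples from it, scores NODF and/or optimized
    Barber Q on the observed matrix and on every null matrix, and
    assembles Z-scores, two-sided empirical tail p-values and verdicts.
    Modularity search effort: ``n_restarts`` restarts on the observed
    matrix, ``null_restarts`` on each null matrix.

    Fully reproducible: the master ``seed`` derives separate substreams
    for ensemble sampling (seed, 1), the observed modularity search
    (seed, 2) and the per-null searches (seed, 3 + s).
    """
    if fit is None:
        fit = fit_bicm(inc)
    results: dict[str, NullEnsembleResult] = {}
    observed_partition: ModulePartition | None = None

    want_nodf = METRIC_NODF in metrics
    want_q = METRIC_Q in metrics
    nodf_obs = _nodf_or_zero(inc) if want_nodf else None
    if want_q:
        observed_partition = optimize_modularity(inc, n_restarts=n_restarts, seed=seed * 7 + 2)
    nodf_null: list[float] = []
    q_null: list[float] = []
    for s, sample in enumerate(iter_ensemble(fit, n_null, seed=seed * 7 + 1)):
        if want_nodf:
            nodf_null.append(_nodf_or_zero(sample))
        if want_q:
            part = optimize_modularity(sample, n_restarts=null_restarts, seed=seed * 7 + 3 + s)
            q_null.append(part.q)
    if want_nodf:
        results[METRIC_NODF] = NullEnsembleResult.from_null_sample(
            METRIC_NODF, nodf_obs, nodf_null
        )
    if want_q:
        results[METRIC_Q] = NullEnsembleResult.from_null_sample(
            METRIC_Q, observed_partition.q, q_null
        )

    verdicts = {}
    if want_nodf:
        verdicts["nestedness"] = results[METRIC_NODF].verdict(("nested", "anti-nested"), alpha)
    if want_q:
        verdicts["modularity"] = results[METRIC_Q].verdict(("modular", "non-modular"), alpha)

    return NetworkReport(
        dataset_id=dataset_id,
        n_rows=inc.n_rows,
        n_cols=inc.n_cols,
        n_links=inc.n_links,
        results=results,
        verdicts=verdicts,
        observed_partition=observed_partition,
        fit_residual=fit.residual,
        fit_iterations=fit.iterations,
        fit_loglik=fit.loglik,
        fit_degenerate=fit.degenerate,
        n_null=n_null,
        n_restarts=n_restarts,
        null_restarts=null_restarts,
        alpha=alpha,
        seed=seed,
    )


def batch_analyze(
    datasets: Iterable[tuple[str, BipartiteIncidence]],
    **kwargs,
) -> list[NetworkReport]:
    """Analyze a sequence of ``(dataset_id, matrix)`` pairs."""
    return [
        analyze_network(inc, dataset_id=dataset_id, **kwargs)
        for dataset_id, inc in datasets
    ]


def summarize_reports(reports: Sequence[NetworkReport]) -> pd.DataFrame:
    """One-row-per-dataset summary table (metrics, z-scores, p-values, verdicts)."""
    rows = []
    for rep in reports:
        row: dict[str, object] = {
            "dataset": rep.dataset_id,
            "n_plants": rep.n_rows,
            "n_fungi": rep.n_cols,
            "n_links": rep.n_links,
        }
        for name, res in rep.results.items():
            row[f"{name}_observed"] = res.observed
            row[f"{name}_null_mean"] = res.null_mean
            row[f"{name}_null_sd"] = res.null_sd
            row[f"{name}_z"] = res.z
            row[f"{name}_p_lower"] = res.p_lower
            row[f"{name}_p_upper"] = res.p_upper
        row.update(rep.verdicts)
        rows.append(row)
    return pd.DataFrame(rows)
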