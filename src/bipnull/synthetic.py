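"""Synthetic bipartite matrices with known structure.

Generators for the matrix archetypes needed to exercise the pipeline
without external data: uniform-random (Erdos-Renyi-style) fill, perfectly
nested left-packed profiles, planted modular block structure, and
degree-heterogeneous Chung-Lu-style matrices emulating the heavy-tailed
degree sequences of real plant-AMF tables (whose published dimensions span
roughly 1-245 plant nodes by 8-277 fungal nodes).

Reproducibility contract: one master integer seed; each generator draws
from a private stream derived from (generator tag, seed); entries are
generated in row-major order.  An identical :class:`SyntheticSpec`
(including the seed) regenerates a bit-identical matrix.
"""

from __future__ import annotations

import dataclasses
import json
import warnings
from typing import Sequence

import numpy as np

from .incidence import BipartiteIncidence, IncidenceError
from .metrics import ModulePartition

__all__ = [
    "SyntheticSpec",
    "gen_random",
    "gen_perfectly_nested",
    "gen_modular",
    "gen_heterogeneous",
]

# stable per-generator tags for private RNG streams
_STREAM = {"random": 1, "nested": 2, "modular": 3, "heterogeneous": 4}


def _labels(prefix: str, n: int) -> tuple[str, ...]:
    width = len(str(n))
    return tuple(f"{prefix}{i + 1:0{width}d}" for i in range(n))


def _rng(generator: str, seed: int) -> np.random.Generator:
    return np.random.default_rng([_STREAM[generator], seed])


def gen_random(n_rows: int, n_cols: int, connectance: float, seed: int = 0) -> BipartiteIncidence:
    """Matrix with i.i.d. Bernoulli(connectance) entries."""
    if not 0.0 <= connectance <= 1.0:
        raise IncidenceError(f"connectance must be in [0, 1], got {connectance}")
    rng = _rng("random", seed)
    entries = (rng.random((n_rows, n_cols)) < connectance).astype(np.int8)
    return BipartiteIncidence(_labels("P", n_rows), _labels("F", n_cols), entries)


def gen_perfectly_nested(
    n_rows: int, n_cols: int, fill_profile: Sequence[int]
) -> BipartiteIncidence:
    """Left-packed, perfectly nested matrix from a strictly decreasing fill profile.

    Row ``i`` carries 1s in its first ``fill_profile[i]`` columns, so every
    row's support strictly contains the support of every lower-fill row
    and NODF is 100 by construction.  Fills must be strictly decreasing,
    at least 1, and no larger than ``n_cols``.
    """
    profile = np.asarray(fill_profile, dtype=np.int64)
    if len(profile) != n_rows:
        raise IncidenceError("fill_profile length must equal n_rows")
    if (np.diff(profile) >= 0).any():
        raise IncidenceError("fill_profile must be strictly decreasing (no ties)")
    if profile[0] > n_cols or profile[-1] < 1:
        raise IncidenceError("fills must lie in [1, n_cols]")
    entries = (np.arange(n_cols) < profile[:, None]).astype(np.int8)
    return BipartiteIncidence(_labels("P", n_rows), _labels("F", n_cols), entries)


def gen_modular(
    module_sizes: Sequence[tuple[int, int]],
    p_in: float,
    p_out: float,
    seed: int = 0,
) -> tuple[BipartiteIncidence, ModulePartition]:
    """Planted-partition matrix: blocks of rows and columns share modules.

    Entry (i, j) is 1 with probability ``p_in`` when row i and column j
    belong to the same planted module and ``p_out`` otherwise.  Returns
    the matrix together with the planted partition (its Q computed on the
    realized matrix) for recovery tests.
    """
    for p, name in ((p_in, "p_in"), (p_out, "p_out")):
        if not 0.0 <= p <= 1.0:
            raise IncidenceError(f"{name} must be in [0, 1], got {p}")
    if any(r < 1 or c < 1 for r, c in module_sizes):
        raise IncidenceError("every module needs at least one row and one column")
    if p_in <= p_out:
        warnings.warn(
            "p_in <= p_out: planted modules will be no denser than the background",
            stacklevel=2,
        )
    row_modules = np.concatenate(
        [np.full(r, m, dtype=np.int64) for m, (r, _) in enumerate(module_sizes)]
    )
    col_modules = np.concatenate(
        [np.full(c, m, dtype=np.int64) for m, (_, c) in enumerate(module_sizes)]
    )
    same = row_modules[:, None] == col_modules[None, :]
    prob = np.where(same, p_in, p_out)
    rng = _rng("modular", seed)
    entries = (rng.random(prob.shape) < prob).astype(np.int8)
    inc = BipartiteIncidence(
        _labels("P", len(row_modules)), _labels("F", len(col_modules)), entries
    )
    return inc, ModulePartition.from_labels(inc, row_modules, col_modules)


def gen_heterogeneous(
    row_weights: Sequence[float],
    col_weights: Sequence[float],
    target_links: float,
    seed: int = 0,
) -> BipartiteIncidence:
    """Chung-Lu-style matrix with heterogeneous expected degrees.

    Entry (i, j) is 1 with probability
    ``min(1, w_i * v_j * target_links / (sum(w) * sum(v)))``; when no
    probability is clipped the expected total link count is
    ``target_links`` and expected degrees are proportional to the weights.
    Edge-probability construction (not stub matching) — no multi-edges,
    matching the Bernoulli sampling of the BiCM ensemble.
    """
    w = np.asarray(row_weights, dtype=float)
    v = np.asarray(col_weights, dtype=float)
    if (w <= 0).any() or (v <= 0).any():
        raise IncidenceError("weights must be strictly positive")
    prob = np.minimum(1.0, np.outer(w, v) * target_links / (w.sum() * v.sum()))
    rng = _rng("heterogeneous", seed)
    entries = (rng.random(prob.shape) < prob).astype(np.int8)
    return BipartiteIncidence(_labels("P", len(w)), _labels("F", len(v)), entries)


@dataclasses.dataclass(frozen=True)
class SyntheticSpec:
    """Declarative description of a synthetic matrix (for CLI sidecars).

    Holds the generator name, dimensions and generator-specific
    parameters; :meth:`realize` dispatches to the matching generator.  An
    identical spec (seed included) regenerates an identical matrix.
    """

    generator: str
    n_rows: int
    n_cols: int
    seed: int = 0
    connectance: float | None = None
    fill_profile: tuple[int, ...] | None = None
    module_sizes: tuple[tuple[int, int], ...] | None = None
    p_in: float | None = None
    p_out: float | None = None
    row_weights: tuple[float, ...] | None = None
    col_weights: tuple[float, ...] | None = None
    target_links: float | None = None

    def realize(self) -> tuple[BipartiteIncidence, ModulePartition | None]:
        if self.generator == "random":
            return gen_random(self.n_rows, self.n_cols, self.connectance, self.seed), None
        if self.generator == "nested":
            return gen_perfectly_nested(self.n_rows, self.n_cols, self.fill_profile), None
        if self.generator == "modular":
            return gen_modular(self.module_sizes, self.p_in, self.p_out, self.seed)
        if self.generator == "heterogeneous":
            return (
                gen_heterogeneous(
                    self.row_weights, self.col_weights, self.target_links, self.seed
                ),
                None,
            )
        raise IncidenceError(f"unknown generator {self.generator!r}")

    def to_json(self) -> str:
        return json.dumps(dataclasses.asdict(self), sort_keys=True)

    @classmethod
    def from_json(cls, text: str) -> "SyntheticSpec":
        raw = json.loads(text)
        for key in ("fill_profile", "row_weights", "col_weights"):
            if raw.get(key) is not None:
                raw[key] = tuple(raw[key])
        if raw.get("module_sizes") is not None:
            raw["module_sizes"] = tuple(tuple(ms) for ms in raw["module_sizes"])
        return cls(**raw)
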