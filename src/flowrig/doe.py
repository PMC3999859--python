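"""Two-level factorial campaign machinery.

Generates replicated, randomised 2^k designs, computes the four response
parameters from NMR integral tables, and estimates main effects and
interactions by contrast differences (equivalently, twice the coefficients
of the orthogonal linear fit), with replicate-pooled standard errors.

A main effect is the mean response at a factor's high (+1) level minus the
mean at its low (-1) level across the whole design; interaction contrasts
are elementwise products of the parent factor columns.  With r >= 2
replicates the pure-error variance pooled over the 2^k cells yields a
standard error and a |t| ratio per term.
"""

from __future__ import annotations

import itertools
import math
from dataclasses import dataclass, field
from typing import Any, Sequence

import numpy as np
import pandas as pd


class DesignError(Exception):
    pass


@dataclass(frozen=True)
class Factor:
    """One two-level factor: physical low/high mapped to coded -1/+1."""

    name: str
    low: Any
    high: Any

    def __post_init__(self) -> None:
        if self.low == self.high:
            raise DesignError(f"factor {self.name!r}: low and high must differ")

    def physical(self, coded: int) -> Any:
        return self.high if coded > 0 else self.low


@dataclass
class RunSpec:
    """One row of the run table."""

    run_id: int
    coded: tuple[int, ...]
    settings: dict[str, Any]
    order: int  # execution position, 0-based
    batch: int  # 0-based valve batch
    port: int  # 1-based sample port within the batch


@dataclass
class FactorialDesign:
    """Replicated full-factorial run list plus measured responses.

    Responses are stored per run id as dicts of named response values.
    """

    factors: list[Factor]
    replicates: int
    runs: list[RunSpec]
    seed: int | None = None
    responses: dict[int, dict[str, float]] = field(default_factory=dict)

    @property
    def k(self) -> int:
        return len(self.factors)

    @property
    def n_runs(self) -> int:
        return len(self.runs)

    @property
    def n_batches(self) -> int:
        return 1 + max(r.batch for r in self.runs)

    def attach_response(self, run_id: int, values: dict[str, float]) -> None:
        self.responses.setdefault(run_id, {}).update(values)

    def in_execution_order(self) -> list[RunSpec]:
        return sorted(self.runs, key=lambda r: r.order)

    def to_frame(self) -> pd.DataFrame:
        """Design + responses as a tidy DataFrame (one row per run)."""
        rows = []
        for r in self.runs:
            row: dict[str, Any] = {"run_id": r.run_id, "order": r.order,
                                   "batch": r.batch, "port": r.port}
            for f, c in zip(self.factors, r.coded):
                row[f"x_{f.name}"] = c
                row[f.name] = r.settings[f.name]
            row.update(self.responses.get(r.run_id, {}))
            rows.append(row)
        return pd.DataFrame(rows).sort_values("order").reset_index(drop=True)


def full_factorial(
    factors: Sequence[Factor],
    replicates: int = 2,
    seed: int | None = None,
    ports: int = 9,
) -> FactorialDesign:
    """All 2^k coded combinations x ``replicates``, in seeded random order.

    Sample ports are assigned cyclically over the multi-position valve's
    ``ports`` outlets; a design larger than one valve's capacity is split
    into consecutive batches of at most ``ports`` runs (e.g. 16 runs on a
    9-port valve execute as batches of 9 and 7).
    """
    if len(factors) < 1:
        raise DesignError("need at least one factor")
    if replicates < 1:
        raise DesignError("need at least one replicate")
    if ports < 1:
        raise DesignError("valve needs at least one port")
    names = [f.name for f in factors]
    if len(names) != len(set(names)):
        raise DesignError("duplicate factor names")

    combos = list(itertools.product((-1, 1), repeat=len(factors)))
    coded_rows = [c for c in combos for _ in range(replicates)]
    order = np.random.default_rng(seed).permutation(len(coded_rows))

    runs = []
    for run_id, coded in enumerate(coded_rows):
        pos = int(order[run_id])
        runs.append(
            RunSpec(
                run_id=run_id,
                coded=coded,
                settings={f.name: f.physical(c) for f, c in zip(factors, coded)},
                order=pos,
                batch=pos // ports,
                port=pos % ports + 1,
            )
        )
    return FactorialDesign(list(factors), replicates, runs, seed=seed)


# ---------------------------------------------------------------------------
# Responses from NMR integral tables
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class ResponseSet:
    """The four response parameters computed per sample.

    From the relative integrals I1 (product), I2 (residual substrate),
    I4 (tetrahydro intermediate) and Ix (unidentified byproduct):

    * ``conversion``  = 1 - I2 / (I1 + I2 + I4 + Ix)
    * ``yield_1``     = I1 / (I1 + I2 + I4 + Ix)
    * ``impurity_4``  = I4 / (I1 + I2)
    * ``impurity_x``  = Ix / (I1 + I2)
    """

    conversion: float
    yield_1: float
    impurity_4: float
    impurity_x: float

    def to_dict(self) -> dict[str, float]:
        return {
            "conversion": self.conversion,
            "yield_1": self.yield_1,
            "impurity_4": self.impurity_4,
            "impurity_x": self.impurity_x,
        }


def compute_responses(i1: float, i2: float, i4: float, ix: float) -> ResponseSet:
    """Responses from one integral row; see :class:`ResponseSet`."""
    if min(i1, i2, i4, ix) < 0:
        raise DesignError("integrals must be non-negative")
    total = i1 + i2 + i4 + ix
    if total == 0:
        raise DesignError("all-zero integral row")
    ref = i1 + i2
    if ref == 0:
        raise DesignError("I1 + I2 = 0: impurity ratios undefined")
    return ResponseSet(
        conversion=1.0 - i2 / total,
        yield_1=i1 / total,
        impurity_4=i4 / ref,
        impurity_x=ix / ref,
    )


# ---------------------------------------------------------------------------
# Effect estimation
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class EffectEstimate:
    """One term of the effects table."""

    term: str  # e.g. "T", "H", "T:H", "T:H:Q"
    estimate: float
    std_error: float  # nan when not estimable (r = 1)
    t_ratio: float  # nan when std_error is nan or zero

    @property
    def order(self) -> int:
        return self.term.count(":") + 1


def _terms(names: Sequence[str]) -> list[tuple[str, tuple[int, ...]]]:
    """All 2^k - 1 model terms as (label, factor-index tuple)."""
    out = []
    for size in range(1, len(names) + 1):
        for idx in itertools.combinations(range(len(names)), size):
            out.append((":".join(names[i] for i in idx), idx))
    return out


def estimate_effects(
    design: FactorialDesign, response: str = "conversion"
) -> list[EffectEstimate]:
    """Main effects and all interactions for one response.

    effect(term) = mean(y | contrast = +1) - mean(y | contrast = -1), the
    contrast being the elementwise product of the term's coded columns.
    With r >= 2, the pure-error variance is pooled over replicate cells
    (df = n - 2^k) and SE(effect) = sqrt(4 s^2 / n).
    """
    missing = [r.run_id for r in design.runs
               if response not in design.responses.get(r.run_id, {})]
    if missing:
        raise DesignError(f"runs missing response {response!r}: {missing}")

    X = np.array([r.coded for r in design.runs], dtype=float)  # n x k
    y = np.array([design.responses[r.run_id][response] for r in design.runs])
    n = len(y)
    names = [f.name for f in design.factors]

    # pooled pure-error variance from replicate cells
    se_effect = math.nan
    if design.replicates >= 2:
        cells: dict[tuple[int, ...], list[float]] = {}
        for r, yi in zip(design.runs, y):
            cells.setdefault(r.coded, []).append(float(yi))
        ss = sum(
            sum((v - np.mean(vals)) ** 2 for v in vals) for vals in cells.values()
        )
        df = n - 2 ** design.k
        if df > 0:
            s2 = ss / df
            se_effect = math.sqrt(4.0 * s2 / n)

    out = []
    for label, idx in _terms(names):
        contrast = X[:, idx].prod(axis=1)
        estimate = float(y[contrast > 0].mean() - y[contrast < 0].mean())
        if math.isnan(se_effect) or se_effect == 0.0:
            t = math.nan
        else:
            t = estimate / se_effect
        out.append(EffectEstimate(label, estimate, se_effect, t))
    return out


def rank_factors(estimates: Sequence[EffectEstimate]) -> list[str]:
    """Terms ordered most-important-first.

    Sorted by |t| when standard errors exist, else by |estimate|; ties (and
    all-nan t ratios) break alphabetically by term label.
    """
    def key(e: EffectEstimate) -> tuple[float, str]:
        score = abs(e.t_ratio) if not math.isnan(e.t_ratio) else abs(e.estimate)
        return (-score, e.term)

    return [e.term for e in sorted(estimates, key=key)]


def significant_terms(estimates: Sequence[EffectEstimate], t_cut: float = 2.0) -> list[str]:
    """Terms whose |t| exceeds ``t_cut`` (the conventional two-ish rule)."""
    return [e.term for e in estimates
            if not math.isnan(e.t_ratio) and abs(e.t_ratio) > t_cut]


def effects_frame(estimates: Sequence[EffectEstimate]) -> pd.DataFrame:
    """Effects table as a DataFrame, ready for CSV export or printing."""
    return pd.DataFrame(
        [
            {"term": e.term, "order": e.order, "estimate": e.estimate,
             "std_error": e.std_error, "t_ratio": e.t_ratio}
            for e in estimates
        ]
    )
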