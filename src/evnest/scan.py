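"""Regulator scans across network variants, expected-value ratios, and trend analysis.

A scan runs one independent nested-sampling estimate per (subnetwork
variant, regulator grid point), with per-point seeds derived
deterministically from the base seed so that scans are reproducible and
resumable.  Trend utilities locate level crossings (by linear
interpolation) and smoothed peaks, and :func:`evr` computes the signed
expected-value-ratio statistic used to compare two networks (a Bayes-factor
analogue with a continuous, antisymmetric range).
"""

from __future__ import annotations

import hashlib
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .apoptosis import RegulatorSetting, build_subnetwork, set_initial
from .network import ReactionNetwork
from .objectives import make_objective
from .sampler import ExpectedValueEstimate, PriorSpec, SamplerConfig, run

logger = logging.getLogger(__name__)

SCAN_COLUMNS = [
    "variant", "regulator_name", "regulator_value", "objective",
    "Z", "error", "n_evaluations", "seed", "status",
]


@dataclass(frozen=True)
class ScanSpec:
    """One expected-value scan: variants x regulator grid.

    ``fixed_overrides`` sets additional initial copy numbers on every grid
    point (e.g. ``{"Bcl2": 0}`` to run a death-primed condition);
    species a variant knocked out are silently inapplicable there and an
    override of a missing species raises at build time.
    """

    variants: tuple[str, ...]
    regulator_name: str
    regulator_values: tuple[float, ...]
    objective: str = "parp_cleavage"
    sampler: SamplerConfig = field(default_factory=SamplerConfig)
    fixed_overrides: dict[str, float] = field(default_factory=dict)
    t_end: float = 20_000.0
    n_points: int = 201

    def __post_init__(self):
        if not self.regulator_values:
            raise ValueError("regulator grid must be nonempty")
        if not self.variants:
            raise ValueError("at least one variant is required")


@dataclass(frozen=True)
class ScanRecord:
    """One (variant, regulator value) expected-value estimate."""

    variant: str
    regulator_name: str
    regulator_value: float
    objective: str
    estimate: ExpectedValueEstimate | None
    seed: int
    status: str = "ok"  # "ok" | "failed"

    def as_row(self) -> dict:
        est = self.estimate
        return {
            "variant": self.variant,
            "regulator_name": self.regulator_name,
            "regulator_value": self.regulator_value,
            "objective": self.objective,
            "Z": est.value if est else np.nan,
            "error": est.error if est else np.nan,
            "n_evaluations": est.n_evaluations if est else 0,
            "seed": self.seed,
            "status": self.status,
        }


def point_seed(base_seed: int, variant: str, index: int) -> int:
    """Deterministic independent seed for one grid point (stable across runs)."""
    digest = hashlib.sha256(f"{base_seed}:{variant}:{index}".encode()).digest()
    return int.from_bytes(digest[:4], "big") % (2**31)


def _configured_network(spec: ScanSpec, variant: str, value: float) -> ReactionNetwork:
    net = build_subnetwork(variant)
    for name, copies in spec.fixed_overrides.items():
        net = set_initial(net, RegulatorSetting(name, copies))
    return set_initial(net, RegulatorSetting(spec.regulator_name, value))


def run_scan(spec: ScanSpec, out_csv: str | Path | None = None) -> list[ScanRecord]:
    """Run independent sampler estimates over the full variant x grid product.

    When ``out_csv`` is given, each record is appended as soon as it
    completes and records already present in the file are not recomputed,
    so interrupted scans resume.  Per-point failures are recorded with
    status ``failed`` and the scan continues.
    """
    done: set[tuple[str, float]] = set()
    path = Path(out_csv) if out_csv else None
    if path is not None and path.exists():
        prev = pd.read_csv(path)
        done = {(str(r.variant), float(r.regulator_value)) for r in prev.itertuples()}
        if done:
            logger.info("resuming scan: %d records already present in %s", len(done), path)

    records: list[ScanRecord] = []
    for variant in spec.variants:
        for index, value in enumerate(spec.regulator_values):
            if (variant, float(value)) in done:
                continue
            seed = point_seed(spec.sampler.seed, variant, index)
            cfg = SamplerConfig(
                n_live=spec.sampler.n_live,
                termination_tol=spec.sampler.termination_tol,
                seed=seed,
                max_evaluations=spec.sampler.max_evaluations,
                proposal=spec.sampler.proposal,
                enlargement=spec.sampler.enlargement,
                max_tries_per_iteration=spec.sampler.max_tries_per_iteration,
            )
            try:
                net = _configured_network(spec, variant, value)
                objective = make_objective(
                    net, spec.objective, t_end=spec.t_end, n_points=spec.n_points
                )
                prior = PriorSpec.for_network(net)
                est = run(objective, prior, cfg)
                rec = ScanRecord(variant, spec.regulator_name, float(value),
                                 spec.objective, est, seed)
            except Exception as exc:
                logger.warning("scan point (%s, %s=%g) failed: %s",
                               variant, spec.regulator_name, value, exc)
                rec = ScanRecord(variant, spec.regulator_name, float(value),
                                 spec.objective, None, seed, status="failed")
            records.append(rec)
            logger.info("scan point done: variant=%s %s=%g Z=%s",
                        variant, spec.regulator_name, value,
                        f"{rec.estimate.value:.4f}" if rec.estimate else "failed")
            if path is not None:
                row = pd.DataFrame([rec.as_row()], columns=SCAN_COLUMNS)
                row.to_csv(path, mode="a", header=not path.exists(), index=False)
    return records


def records_to_frame(records: list[ScanRecord]) -> pd.DataFrame:
    return pd.DataFrame([r.as_row() for r in records], columns=SCAN_COLUMNS)


def evr(
    z1: ExpectedValueEstimate | float,
    z2: ExpectedValueEstimate | float,
    eps: float = 1e-12,
) -> float:
    """Signed expected-value ratio of two estimates.

    Returns ``Z1/Z2 - 1`` when ``Z1 > Z2``, ``-Z2/Z1 + 1`` when
    ``Z1 < Z2`` and 0 at equality: antisymmetric, zero at equality, and
    continuous across ``Z1 == Z2``.  Values at or below ``eps`` make the
    ratio undefined and raise.
    """
    v1 = float(z1.value if isinstance(z1, ExpectedValueEstimate) else z1)
    v2 = float(z2.value if isinstance(z2, ExpectedValueEstimate) else z2)
    if v1 <= eps or v2 <= eps:
        raise ValueError(f"expected-value ratio undefined for Z <= {eps}: ({v1}, {v2})")
    if v1 > v2:
        return v1 / v2 - 1.0
    if v1 < v2:
        return -v2 / v1 + 1.0
    return 0.0


def evr_series(
    records: list[ScanRecord], numerator_variant: str, denominator_variant: str
) -> pd.DataFrame:
    """EVR at each shared grid point of two variants' scan records."""
    frame = records_to_frame(records)
    num = frame[(frame.variant == numerator_variant) & (frame.status == "ok")]
    den = frame[(frame.variant == denominator_variant) & (frame.status == "ok")]
    merged = num.merge(den, on="regulator_value", suffixes=("_num", "_den"))
    rows = [
        {
            "regulator_value": r.regulator_value,
            "numerator_variant": numerator_variant,
            "denominator_variant": denominator_variant,
            "evr": evr(float(r.Z_num), float(r.Z_den)),
        }
        for r in merged.itertuples()
    ]
    return pd.DataFrame(rows, columns=["regulator_value", "numerator_variant",
                                       "denominator_variant", "evr"])


def find_crossing(
    regulator_values: np.ndarray, z_values: np.ndarray, level: float = 0.5
) -> float | None:
    """Regulator value of the first downward crossing of ``level``.

    The series must be ordered by regulator value.  The crossing is located
    by linear interpolation between the bracketing grid points; an exact
    grid hit returns that grid value.  Returns ``None`` when the series
    never crosses downward.  Noisy series with several crossings return the
    first and log the count.
    """
    x = np.asarray(regulator_values, dtype=float)
    z = np.asarray(z_values, dtype=float)
    if np.any(np.diff(x) <= 0):
        raise ValueError("series must be strictly ordered by regulator value")
    crossings = []
    for i in range(len(z) - 1):
        if z[i] >= level > z[i + 1]:
            if z[i] == level:
                crossings.append(float(x[i]))
            else:
                frac = (z[i] - level) / (z[i] - z[i + 1])
                crossings.append(float(x[i] + frac * (x[i + 1] - x[i])))
    if z[-1] == level and not crossings:
        crossings.append(float(x[-1]))
    if not crossings:
        return None
    if len(crossings) > 1:
        logger.warning("series crosses level %g %d times; returning the first",
                       level, len(crossings))
    return crossings[0]


def find_peak(
    regulator_values: np.ndarray, series: np.ndarray, window: int = 5
) -> float | None:
    """Regulator value of the maximum after centered moving-average smoothing.

    ``window`` is the smoothing width in grid points (1 = raw argmax; edges
    use the available points).  Ties return the smallest regulator value;
    an all-equal series has no peak and returns ``None`` with a warning.
    """
    x = np.asarray(regulator_values, dtype=float)
    y = np.asarray(series, dtype=float)
    if len(y) < 3:
        raise ValueError("peak detection needs a series of length >= 3")
    if np.all(y == y[0]):
        logger.warning("series is constant; no peak")
        return None
    smooth = (
        pd.Series(y).rolling(window, center=True, min_periods=1).mean().to_numpy()
    )
    return float(x[int(np.argmax(smooth))])


def precision_study(
    objective,
    prior: PriorSpec,
    populations: list[int],
    n_replicates: int = 3,
    base_seed: int = 0,
    termination_tol: float = 1e-4,
) -> pd.DataFrame:
    """Evaluation counts and reported errors as the live population grows.

    Runs ``n_replicates`` independently seeded estimates per population
    size and aggregates mean evaluations, mean reported error, and the
    empirical spread of Z.  Evaluation counts are expected to roughly
    double per doubling of the population, while errors shrink roughly as
    ``n_live**-0.5``.
    """
    if len(populations) < 2:
        raise ValueError("precision study needs at least 2 population sizes")
    if n_replicates < 3:
        raise ValueError("precision study needs at least 3 replicates")
    rows = []
    for n_live in populations:
        zs, errs, evals = [], [], []
        for rep in range(n_replicates):
            cfg = SamplerConfig(
                n_live=n_live,
                termination_tol=termination_tol,
                seed=point_seed(base_seed, f"n{n_live}", rep),
            )
            est = run(objective, prior, cfg)
            zs.append(est.value)
            errs.append(est.error)
            evals.append(est.n_evaluations)
        rows.append({
            "n_live": n_live,
            "mean_evaluations": float(np.mean(evals)),
            "mean_error": float(np.mean(errs)),
            "mean_Z": float(np.mean(zs)),
            "std_Z": float(np.std(zs, ddof=1)),
            "n_replicates": n_replicates,
        })
    return pd.DataFrame(rows)
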