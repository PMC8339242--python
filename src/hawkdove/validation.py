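"""Empirical interaction strengths from co-culture vs monoculture abundances.

Let ``x(t), y(t)`` be the abundances of the larger (X) and smaller (Y)
strain in co-culture, and ``x0(t), y0(t)`` the same strains grown alone.
The empirical strengths are

* mutualism  ``Mu(t) = (x/x0 + y/y0) / 2`` — the mean co/mono fold change;
  ``Mu > 1`` marks the cooperation region, ``Mu < 1`` competition;
* aggression ``Ag(t) = (x/y) / (x0/y0)`` — how much the larger strain gains
  relative to the smaller upon socialization;
* altruism   ``Al(t) = (y/y0) / (x/x0)`` — how much the smaller strain's
  fold change exceeds the larger's.  Algebraically ``Al * Ag == 1``.

Validation then correlates, within each growth phase, the mathematical
descriptors (``z_mu, z_ag, z_al`` evaluated on co-culture abundances at each
time point) with the matching empirical strengths, pooling all pairs x time
points within a phase.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .descriptors import DegenerateDyadError, SizePair, compute_descriptors
from .growth import (
    AbundanceSeries,
    PHASE_CUTOFF_DEFAULT,
    fit_all_models,
    partition_phases,
    select_model,
)

PHASES = ("lag", "linear", "asymptotic")


class AlignmentError(ValueError):
    """Co-culture and monoculture series do not share a time grid / strains."""


@dataclass(frozen=True)
class StrengthSeries:
    """Time-indexed empirical Mu/Ag/Al for one co-culture pair."""

    pair_id: str
    times: np.ndarray
    mu: np.ndarray
    ag: np.ndarray
    al: np.ndarray
    region: np.ndarray  # "competition" (Mu < 1) or "cooperation" (Mu > 1)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "pair_id": self.pair_id,
                "time": self.times,
                "Mu": self.mu,
                "Ag": self.ag,
                "Al": self.al,
                "region": self.region,
            }
        )


@dataclass(frozen=True)
class PhaseCorrelation:
    """Descriptor-vs-strength correlation within one growth phase."""

    phase: str
    descriptor: str  # z_mu | z_ag | z_al
    r: float
    p: float
    n: int
    method: str = "pearson"


def _check_aligned(a: AbundanceSeries, b: AbundanceSeries):
    if not np.allclose(a.times, b.times):
        raise AlignmentError(
            f"series {a.strain_id!r}/{a.condition!r} and {b.strain_id!r}/"
            f"{b.condition!r} are on different time grids"
        )


def empirical_strengths(
    co: tuple[AbundanceSeries, AbundanceSeries],
    mono: tuple[AbundanceSeries, AbundanceSeries],
    ordering: str = "per_time",
) -> StrengthSeries:
    """Compute Mu/Ag/Al per shared time point for one strain pair.

    Parameters
    ----------
    co, mono
        The two strains' series in co-culture and monoculture.  Strain ids
        must match between conditions and all four series must share one
        strictly increasing time grid.
    ordering
        "per_time" (default): X is the more abundant strain in co-culture
        at each time point, re-evaluated per time.  "fixed": X is the
        strain with the larger mean co-culture abundance, held fixed over
        the whole series.
    """
    co_a, co_b = co
    mono_map = {s.strain_id: s for s in mono}
    if set(mono_map) != {co_a.strain_id, co_b.strain_id}:
        raise AlignmentError(
            f"monoculture strains {sorted(mono_map)} do not match co-culture "
            f"strains {sorted([co_a.strain_id, co_b.strain_id])}"
        )
    mono_a, mono_b = mono_map[co_a.strain_id], mono_map[co_b.strain_id]
    for s in (co_b, mono_a, mono_b):
        _check_aligned(co_a, s)

    a, b = co_a.values, co_b.values
    a0, b0 = mono_a.values, mono_b.values

    if ordering == "fixed":
        a_is_x = np.full(len(a), a.mean() >= b.mean())
    elif ordering == "per_time":
        a_is_x = a >= b
    else:
        raise ValueError(f"ordering must be 'per_time' or 'fixed', got {ordering!r}")

    x = np.where(a_is_x, a, b)
    y = np.where(a_is_x, b, a)
    x0 = np.where(a_is_x, a0, b0)
    y0 = np.where(a_is_x, b0, a0)

    mu = (x / x0 + y / y0) / 2.0
    ag = (x / y) / (x0 / y0)
    al = (y / y0) / (x / x0)
    region = np.where(mu < 1.0, "competition", "cooperation")
    return StrengthSeries(
        pair_id=co_a.pair_id or co_b.pair_id,
        times=co_a.times.copy(),
        mu=mu,
        ag=ag,
        al=al,
        region=region,
    )


def descriptor_series(co: tuple[AbundanceSeries, AbundanceSeries]) -> pd.DataFrame:
    """z_mu/z_ag/z_al evaluated on co-culture abundances at each time point.

    X is the more abundant strain at each time; time points where the two
    abundances are degenerate (equal within the guard) yield NaN descriptors
    and are dropped by the correlation step.
    """
    co_a, co_b = co
    _check_aligned(co_a, co_b)
    rows = []
    for t, va, vb in zip(co_a.times, co_a.values, co_b.values):
        try:
            p = SizePair.from_traits(co_a.strain_id, va, co_b.strain_id, vb)
            d = compute_descriptors(p)
            rows.append({"time": t, "z_mu": d.z_mu, "z_ag": d.z_ag, "z_al": d.z_al})
        except DegenerateDyadError:
            rows.append({"time": t, "z_mu": np.nan, "z_ag": np.nan, "z_al": np.nan})
    out = pd.DataFrame(rows)
    out.insert(0, "pair_id", co_a.pair_id or co_b.pair_id)
    return out


_DESCRIPTOR_TO_STRENGTH = {"z_mu": "Mu", "z_ag": "Ag", "z_al": "Al"}


def descriptor_strength_correlation(
    table: pd.DataFrame, method: str = "pearson", min_n: int = 3
) -> list[PhaseCorrelation]:
    """Per-phase correlation of each descriptor with its empirical strength.

    ``table`` pools all pairs x time points and must carry columns
    ``phase, z_mu, z_ag, z_al, Mu, Ag, Al``.  Phases with fewer than
    ``min_n`` complete observations, or with zero variance on either side,
    are skipped with a warning.
    """
    if method not in ("pearson", "spearman"):
        raise ValueError(f"method must be 'pearson' or 'spearman', got {method!r}")
    corr = stats.pearsonr if method == "pearson" else stats.spearmanr
    out = []
    for phase in PHASES:
        sub = table[table["phase"] == phase]
        for z_col, s_col in _DESCRIPTOR_TO_STRENGTH.items():
            pairdf = sub[[z_col, s_col]].dropna()
            if len(pairdf) < min_n:
                warnings.warn(
                    f"phase {phase!r}: only {len(pairdf)} complete observations "
                    f"for {z_col} vs {s_col}; correlation skipped",
                    stacklevel=2,
                )
                continue
            zv, sv = pairdf[z_col].to_numpy(), pairdf[s_col].to_numpy()
            if np.ptp(zv) == 0 or np.ptp(sv) == 0:
                warnings.warn(
                    f"phase {phase!r}: zero variance in {z_col} vs {s_col}; "
                    "correlation undefined, skipped",
                    stacklevel=2,
                )
                continue
            res = corr(zv, sv)
            out.append(
                PhaseCorrelation(
                    phase=phase,
                    descriptor=z_col,
                    r=float(res.statistic),
                    p=float(res.pvalue),
                    n=len(pairdf),
                    method=method,
                )
            )
    return out


def correlations_frame(correlations: list[PhaseCorrelation]) -> pd.DataFrame:
    return pd.DataFrame([c.__dict__ for c in correlations])


class CocultureStudy:
    """End-to-end validation arm for a cohort of strain pairs.

    Built from a long-format abundance table with columns
    ``pair_id, strain_id, condition, time, abundance`` (condition in
    {monoculture, coculture}).  ``fit()`` fits growth curves, partitions
    phases, computes empirical strengths and descriptors, and correlates
    them per phase.
    """

    REQUIRED = ("pair_id", "strain_id", "condition", "time", "abundance")

    def __init__(self, frame: pd.DataFrame, ordering: str = "per_time",
                 phase_cutoff: float = PHASE_CUTOFF_DEFAULT):
        missing = [c for c in self.REQUIRED if c not in frame.columns]
        if missing:
            raise ValueError(f"abundance table is missing columns {missing}")
        bad = set(frame["condition"].unique()) - {"monoculture", "coculture"}
        if bad:
            raise ValueError(f"unknown condition values {sorted(bad)}")
        self.frame = frame
        self.ordering = ordering
        self.phase_cutoff = phase_cutoff

    @classmethod
    def from_csv(cls, path, **kw):
        return cls(pd.read_csv(path), **kw)

    def _series(self, sub, pair_id) -> AbundanceSeries:
        sub = sub.sort_values("time")
        return AbundanceSeries(
            times=sub["time"].to_numpy(float),
            values=sub["abundance"].to_numpy(float),
            strain_id=str(sub["strain_id"].iloc[0]),
            condition=str(sub["condition"].iloc[0]),
            pair_id=str(pair_id),
        )

    def fit(self, method: str = "pearson", seed: int = 0) -> "CocultureResults":
        """Run the full validation arm; returns a results object."""
        records = []
        fit_rows = []
        for pair_id, g in self.frame.groupby("pair_id", sort=True):
            series = {
                (cond, strain): self._series(sub, pair_id)
                for (cond, strain), sub in g.groupby(["condition", "strain_id"], sort=True)
            }
            strains = sorted({s for (_, s) in series})
            if len(strains) != 2:
                raise ValueError(f"pair {pair_id!r} has strains {strains}; expected 2")
            try:
                co = (series[("coculture", strains[0])], series[("coculture", strains[1])])
                mono = (series[("monoculture", strains[0])], series[("monoculture", strains[1])])
            except KeyError as e:
                raise ValueError(f"pair {pair_id!r} is missing a condition/strain series") from e

            strengths = empirical_strengths(co, mono, ordering=self.ordering)
            zdesc = descriptor_series(co)

            # phase labels come from the larger (more abundant on average)
            # strain's co-culture fit
            lead = co[0] if co[0].values.mean() >= co[1].values.mean() else co[1]
            best = select_model(fit_all_models(lead, seed=seed))
            part = partition_phases(best, cutoff=self.phase_cutoff)
            fit_rows.append(
                {
                    "pair_id": str(pair_id),
                    "strain_id": lead.strain_id,
                    "model": best.model,
                    "A": best.A,
                    "mu_m": best.mu_m,
                    "lam": best.lam,
                    "rss": best.rss,
                    "t_lag_end": part.t_lag_end,
                    "t_linear_end": part.t_linear_end,
                }
            )
            merged = strengths.to_frame().merge(zdesc, on=["pair_id", "time"])
            merged["phase"] = part.labels
            records.append(merged)

        table = pd.concat(records, ignore_index=True)
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            corrs = descriptor_strength_correlation(table, method=method)
        return CocultureResults(table, correlations_frame(corrs),
                                pd.DataFrame(fit_rows), method)


class CocultureResults:
    """Strength/descriptor table, per-pair growth fits, phase correlations."""

    def __init__(self, table, correlations, fits, method):
        self.table = table
        self.correlations = correlations
        self.fits = fits
        self.method = method

    def phase_r(self, descriptor: str, phase: str) -> float:
        sub = self.correlations
        row = sub[(sub["descriptor"] == descriptor) & (sub["phase"] == phase)]
        if row.empty:
            raise KeyError(f"no correlation computed for {descriptor} in phase {phase!r}")
        return float(row["r"].iloc[0])

    def summary(self) -> str:
        lines = [
            "Co-culture validation",
            "=" * 52,
            f"pairs: {self.table['pair_id'].nunique()}   "
            f"observations: {len(self.table)}   method: {self.method}",
            "",
            self.correlations.to_string(index=False),
        ]
        return "\n".join(lines)
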