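"""Seeded generators for every input the pipeline consumes.

Three generators with known ground truth:

* :func:`generate_cohort` — a positive-valued trait cohort (body masses of a
  full-sib family; log-normal), optionally with planted tiers whose
  cross-tier size-ratio means land in requested bands around the decision
  thresholds;
* :func:`generate_coculture` — paired co-culture / monoculture abundance
  trajectories from coupled logistic (gLV-style) dynamics with controllable
  interaction sign and strength, sampled on the 2-h / 4-h schedule and
  observed with multiplicative log-normal noise.  The coupled-logistic
  mechanism is a stand-in data generator: validation only requires that
  co/mono ratios encode the interaction sign;
* :func:`generate_fullsib_genotypes` — Mendelian full-sib genotypes from
  two parents with per-SNP segregating cross types.

All generators are pure functions of their spec plus seed.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.integrate import solve_ivp

#: qPCR sampling schedule: every 2 h to 24 h, then every 4 h to 36 h.
DEFAULT_SCHEDULE = tuple(np.arange(0.0, 25.0, 2.0)) + (28.0, 32.0, 36.0)


# --- trait cohorts ---------------------------------------------------------


@dataclass(frozen=True)
class CohortSpec:
    """Spec for a positive trait cohort.

    Defaults emulate a ~71-individual full-sib family of adult carp: body
    masses log-normal with median 600 (grams) and log-sd 0.30.
    """

    n: int = 71
    median: float = 600.0
    log_sd: float = 0.30
    tier_sizes: tuple[int, ...] | None = None
    ratio_bands: tuple[tuple[float, float], ...] | None = None
    seed: int = 0

    def __post_init__(self):
        if self.n < 3:
            raise ValueError(f"cohort needs n >= 3, got {self.n}")
        if (self.tier_sizes is None) != (self.ratio_bands is None):
            raise ValueError("tier_sizes and ratio_bands must be given together")
        if self.tier_sizes is not None:
            if len(self.ratio_bands) != len(self.tier_sizes) - 1:
                raise ValueError("need one ratio band per adjacent tier pair")
            if sum(self.tier_sizes) > self.n:
                raise ValueError("tier sizes exceed cohort size")
            for lo, hi in self.ratio_bands:
                if not 0 < lo < hi:
                    raise ValueError(f"infeasible ratio band ({lo}, {hi})")


def generate_cohort(spec: CohortSpec) -> pd.DataFrame:
    """Trait table (id, trait[, tier]); reproducible given the seed.

    With planted tiers, tier 0 sits at the top of the size distribution and
    each subsequent tier's values are drawn so that the mean of all
    cross-tier ratios (tier i+1 member / tier i member) lands inside the
    requested band; draws are rejection-checked (up to 200 retries).
    """
    rng = np.random.default_rng(spec.seed)
    ids = [f"F{i + 1:03d}" for i in range(spec.n)]

    if spec.tier_sizes is None:
        traits = spec.median * np.exp(rng.normal(0.0, spec.log_sd, size=spec.n))
        traits = _ensure_distinct(traits, rng)
        return pd.DataFrame({"id": ids, "trait": traits})

    tiers_values: list[np.ndarray] = []
    top_n = spec.tier_sizes[0]
    top = spec.median * np.exp(np.abs(rng.normal(0.0, spec.log_sd, size=top_n)))
    tiers_values.append(top)
    for size, (lo, hi) in zip(spec.tier_sizes[1:], spec.ratio_bands):
        upper = tiers_values[-1]
        # mean over cross pairs of l/u equals mean(l) * mean(1/u); anchor on
        # the harmonic mean of the upper tier so drawn ratios transfer
        u_ref = 1.0 / np.mean(1.0 / upper)
        for attempt in range(200):
            r = rng.uniform(lo, hi, size=size)
            vals = u_ref * r
            realized = np.mean([v / u for u in upper for v in vals])
            if lo < realized < hi:
                break
        else:
            raise ValueError(
                f"could not realize mean cross-tier ratio in band ({lo}, {hi})"
            )
        tiers_values.append(vals)

    n_assigned = sum(spec.tier_sizes)
    rest = spec.n - n_assigned
    traits_list = list(np.concatenate(tiers_values))
    tier_labels = [f"tier{i}" for i, size in enumerate(spec.tier_sizes) for _ in range(size)]
    if rest:
        extra = spec.median * np.exp(rng.normal(0.0, spec.log_sd, size=rest))
        traits_list += list(extra)
        tier_labels += ["untiered"] * rest
    traits = _ensure_distinct(np.asarray(traits_list), rng)
    return pd.DataFrame({"id": ids[: len(traits)], "trait": traits, "tier": tier_labels})


def _ensure_distinct(traits: np.ndarray, rng: np.random.Generator) -> np.ndarray:
    """Nudge exact duplicates (probability ~0 for continuous draws)."""
    while len(np.unique(traits)) != len(traits):  # pragma: no cover
        traits = traits * (1.0 + rng.uniform(-1e-9, 1e-9, size=len(traits)))
    return traits


# --- co-culture growth trajectories ---------------------------------------


@dataclass(frozen=True)
class CocultureSpec:
    """Spec for paired co-culture/monoculture growth trajectories.

    Each pair holds two strains with their own logistic parameters
    (asymptote A, Zwietering maximum slope mu_m, lag lam) and signed
    interaction couplings a_xy (effect of strain y on strain x) and a_yx.
    Couplings default to symmetric draws from ``coupling_range``; pass
    explicit ``couplings`` to override.  Monoculture is the zero-coupling
    limit of the same dynamics.  Abundances are in arbitrary qPCR units
    (asymptotes near 1).

    With ``shared_kinetics`` (default) the two strains of a pair share one
    per-capita growth rate and one lag — they are grown in the same medium
    and differ in carrying capacity — so their uncoupled trajectories stay
    proportional and never cross; ``mu_range`` then draws the larger
    strain's maximum slope and the smaller strain's is scaled by A_y/A_x.
    Set it False for fully independent per-strain kinetics.
    """

    n_pairs: int = 40
    a_x_range: tuple[float, float] = (0.9, 1.2)
    a_y_range: tuple[float, float] = (0.5, 0.75)
    mu_range: tuple[float, float] = (0.08, 0.14)
    lam_range: tuple[float, float] = (2.0, 5.0)
    shared_kinetics: bool = True
    coupling_range: tuple[float, float] = (0.0, 0.6)
    symmetric: bool = True
    couplings: tuple[tuple[float, float], ...] | None = None
    noise_sd: float = 0.05
    n0_frac: float = 0.01
    schedule: tuple[float, ...] = DEFAULT_SCHEDULE
    seed: int = 0

    def __post_init__(self):
        if self.n_pairs < 1:
            raise ValueError("need at least one pair")
        if self.couplings is not None and len(self.couplings) != self.n_pairs:
            raise ValueError("couplings must list one (a_xy, a_yx) per pair")
        if self.noise_sd < 0:
            raise ValueError("noise_sd must be non-negative")
        t = np.asarray(self.schedule)
        if len(t) < 6 or np.any(np.diff(t) <= 0):
            raise ValueError("schedule must be >= 6 strictly increasing times")


def _lag_switch(t, lam, steep=2.0):
    return 1.0 / (1.0 + np.exp(-steep * (t - lam)))


def _coupled_logistic(t_eval, params_x, params_y, a_xy, a_yx, n0_frac):
    """Integrate the coupled logistic system and evaluate on the schedule.

    dN_x/dt = r_x s_x(t) N_x (1 - N_x/A_x + a_xy N_y/A_y)  and symmetrically
    for y; r = 4 mu_m / A converts the Zwietering maximum slope to the
    per-capita rate; s(t) is a smooth lag switch centred at lam.
    """
    A_x, mu_x, lam_x = params_x
    A_y, mu_y, lam_y = params_y
    r_x, r_y = 4.0 * mu_x / A_x, 4.0 * mu_y / A_y

    def rhs(t, n):
        nx_, ny_ = n
        dx = r_x * _lag_switch(t, lam_x) * nx_ * (1.0 - nx_ / A_x + a_xy * ny_ / A_y)
        dy = r_y * _lag_switch(t, lam_y) * ny_ * (1.0 - ny_ / A_y + a_yx * nx_ / A_x)
        return [dx, dy]

    n0 = [n0_frac * A_x, n0_frac * A_y]
    sol = solve_ivp(
        rhs, (t_eval[0], t_eval[-1]), n0, t_eval=t_eval, method="RK45",
        rtol=1e-8, atol=1e-12,
    )
    if not sol.success or np.any(sol.y <= 0):
        raise ValueError(
            f"coupled-logistic integration failed or produced non-positive "
            f"abundance (a_xy={a_xy}, a_yx={a_yx}): {sol.message}"
        )
    return sol.y[0], sol.y[1]


def _interaction_label(a_xy, a_yx):
    if a_xy == 0 and a_yx == 0:
        return "neutral"
    if a_xy > 0 and a_yx > 0:
        return "mutualistic"
    if a_xy < 0 and a_yx < 0:
        return "competitive"
    return "exploitative"


def generate_coculture(spec: CocultureSpec) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Generate the abundance table and its ground-truth labels.

    Returns
    -------
    (abundances, truth)
        ``abundances``: long-format frame with columns pair_id, strain_id,
        condition, time, abundance — four series per pair.
        ``truth``: one row per pair with the drawn parameters, couplings and
        interaction label.
    """
    rng = np.random.default_rng(spec.seed)
    t_eval = np.asarray(spec.schedule, dtype=float)
    rows, truth_rows = [], []
    for i in range(spec.n_pairs):
        pair_id = f"P{i + 1:03d}"
        A_x = rng.uniform(*spec.a_x_range)
        A_y = rng.uniform(*spec.a_y_range)
        mu_x = rng.uniform(*spec.mu_range)
        lam_x = rng.uniform(*spec.lam_range)
        if spec.shared_kinetics:
            # equal per-capita rate (4 mu/A) and equal lag across the pair
            mu_y, lam_y = mu_x * A_y / A_x, lam_x
        else:
            mu_y = rng.uniform(*spec.mu_range)
            lam_y = rng.uniform(*spec.lam_range)
        params_x = (A_x, mu_x, lam_x)
        params_y = (A_y, mu_y, lam_y)
        if spec.couplings is not None:
            a_xy, a_yx = spec.couplings[i]
        elif spec.symmetric:
            a_xy = a_yx = rng.uniform(*spec.coupling_range)
        else:
            a_xy = rng.uniform(*spec.coupling_range)
            a_yx = rng.uniform(*spec.coupling_range)

        co_x, co_y = _coupled_logistic(t_eval, params_x, params_y, a_xy, a_yx, spec.n0_frac)
        mono_x, mono_y = _coupled_logistic(t_eval, params_x, params_y, 0.0, 0.0, spec.n0_frac)

        for strain, co_v, mono_v in (("X", co_x, mono_x), ("Y", co_y, mono_y)):
            for cond, vals in (("coculture", co_v), ("monoculture", mono_v)):
                noisy = vals * np.exp(rng.normal(0.0, spec.noise_sd, size=len(vals))) \
                    if spec.noise_sd > 0 else vals
                for t, v in zip(t_eval, noisy):
                    rows.append(
                        {"pair_id": pair_id, "strain_id": strain,
                         "condition": cond, "time": t, "abundance": v}
                    )
        truth_rows.append(
            {"pair_id": pair_id, "A_x": params_x[0], "mu_x": params_x[1],
             "lam_x": params_x[2], "A_y": params_y[0], "mu_y": params_y[1],
             "lam_y": params_y[2], "a_xy": a_xy, "a_yx": a_yx,
             "label": _interaction_label(a_xy, a_yx)}
        )
    return pd.DataFrame(rows), pd.DataFrame(truth_rows)


# --- full-sib genotypes ----------------------------------------------------

CROSS_TYPES = ("ABxAB", "ABxAA", "AAxAB")

#: Offspring genotype (count of the B allele) distributions per cross type.
_CROSS_DIST = {
    "ABxAB": ([0, 1, 2], [0.25, 0.5, 0.25]),
    "ABxAA": ([0, 1], [0.5, 0.5]),
    "AAxAB": ([0, 1], [0.5, 0.5]),
}


def generate_fullsib_genotypes(
    n: int,
    m_snps: int,
    seed: int = 0,
    cross_probs: tuple[float, float, float] = (0.5, 0.25, 0.25),
) -> pd.DataFrame:
    """Mendelian full-sib genotype matrix (individuals x SNPs, codes 0/1/2).

    Per SNP a segregating parental cross type is drawn (AB x AB, AB x AA,
    AA x AB with ``cross_probs``) and offspring genotypes follow Mendelian
    segregation.  The drawn cross types are stored in
    ``result.attrs["cross_types"]``.
    """
    if n < 2:
        raise ValueError("need at least 2 sibs")
    if m_snps < 1:
        raise ValueError("need at least 1 SNP")
    rng = np.random.default_rng(seed)
    crosses = rng.choice(CROSS_TYPES, size=m_snps, p=cross_probs)
    geno = np.empty((n, m_snps), dtype=np.int8)
    for j, cross in enumerate(crosses):
        codes, probs = _CROSS_DIST[cross]
        geno[:, j] = rng.choice(codes, size=n, p=probs)
    ids = [f"F{i + 1:03d}" for i in range(n)]
    snps = [f"snp{j + 1}" for j in range(m_snps)]
    out = pd.DataFrame(geno, index=ids, columns=snps)
    out.attrs["cross_types"] = list(map(str, crosses))
    return out


def expected_ibs(cross_probs: tuple[float, float, float] = (0.5, 0.25, 0.25)) -> float:
    """Analytic expected pairwise IBS similarity for a full-sib pair.

    Per cross type the expected allele-sharing (2 - |g_i - g_j|)/2 over two
    independent Mendelian draws: AB x AB gives 5/8 (E|g_i - g_j| = 3/4);
    AB x AA (either order) gives 3/4.  The mix is weighted by
    ``cross_probs``.
    """
    per_cross = {"ABxAB": 5.0 / 8.0, "ABxAA": 0.75, "AAxAB": 0.75}
    return float(sum(p * per_cross[c] for c, p in zip(CROSS_TYPES, cross_probs)))
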