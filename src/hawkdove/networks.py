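"""Trait-based social networks, hierarchy roles, and threshold-ratio tests.

For a cohort of n individuals with positive trait values (body masses), all
n(n-1)/2 dyads receive one descriptor value per interaction type.  Culling
the small values (keeping the top fraction ``q``) yields four sparse
networks:

* mutualism / antagonism — undirected;
* aggression / altruism  — directed from the larger to the smaller member
  (a hawk aggresses upon a dove; an altruist benefits an egoist).

A fifth, the relatedness network, comes from genome-wide SNP similarity
(allele-sharing IBS fraction) rather than from the trait.

Role assignment follows degree structure: hubs of the mutualism network
(degree well above the cohort average: > mean + k*sd) are primary leaders,
their neighbours secondary leaders, and so on down to followers; in the
directed networks nodes split into pure actors (out-edges only), pure
recipients (in-edges only), and mixed roles.  Cross-tier body-mass ratios
are then tested against the decision-model thresholds (phi, 1 - phi).
"""

from __future__ import annotations

import itertools
import warnings
from dataclasses import dataclass, field

import networkx as nx
import numpy as np
import pandas as pd
from scipy import stats

from .descriptors import DegenerateDyadError, SizePair, compute_descriptors
from .decision import FIB_MARK, PHI  # noqa: F401  (thresholds used by callers)

NETWORK_TYPES = ("mutualism", "antagonism", "aggression", "altruism", "relatedness")
_DIRECTED = {"aggression", "altruism"}

_DESCRIPTOR_FIELD = {
    "mutualism": "z_mu",
    "antagonism": "z_an",
    "aggression": "z_ag",
    "altruism": "z_al",
}


@dataclass
class InteractionNetwork:
    """One typed, weighted interaction network over the cohort.

    ``all_pairs`` keeps the pre-culling descriptor (or similarity) value for
    every dyad, indexed by the sorted id pair — between-network correlations
    are computed on these full vectors so they align across types.
    """

    net_type: str
    graph: nx.Graph | nx.DiGraph
    sparsity: float  # retained-edge fraction q
    all_pairs: pd.Series = field(repr=False)

    @property
    def directed(self) -> bool:
        return self.net_type in _DIRECTED

    def edge_frame(self) -> pd.DataFrame:
        rows = [
            {"source": u, "target": v, "weight": d["weight"]}
            for u, v, d in self.graph.edges(data=True)
        ]
        return pd.DataFrame(rows, columns=["source", "target", "weight"])


@dataclass
class RoleAssignment:
    """Per-node role labels for one network."""

    net_type: str
    roles: dict[str, str]
    graph: nx.Graph | nx.DiGraph | None = field(default=None, repr=False)

    def tier(self, label: str) -> list[str]:
        return sorted(n for n, r in self.roles.items() if r == label)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            sorted(self.roles.items()), columns=["id", "role"]
        ).assign(network=self.net_type)

    @classmethod
    def from_labels(cls, net_type: str, labels: dict[str, str]) -> "RoleAssignment":
        """Build directly from node -> tier labels (no underlying graph)."""
        return cls(net_type, dict(labels), graph=None)


@dataclass(frozen=True)
class TierRatioResult:
    """Cross-tier trait-ratio test against a fixed threshold."""

    net_type: str
    tier_pair: tuple[str, str]  # (lower tier, upper tier)
    ratios: np.ndarray
    mean_ratio: float
    threshold: float
    statistic: float
    p: float
    direction: str  # "above" | "below"
    alternative: str  # "greater" | "less"
    p_perm: float | None = None


def _dyad_key(a, b) -> tuple[str, str]:
    return (a, b) if str(a) <= str(b) else (b, a)


def all_pairs_descriptors(
    traits: pd.Series, eps: float = 1e-9, on_degenerate: str = "raise"
) -> pd.DataFrame:
    """Descriptor values for every dyad, indexed by sorted id pair.

    ``on_degenerate``: "raise" or "skip" (skipped dyads reported via warning).
    """
    traits = pd.Series(traits, dtype=float)
    rows, index, skipped = [], [], []
    for a, b in itertools.combinations(sorted(traits.index, key=str), 2):
        try:
            p = SizePair.from_traits(a, traits[a], b, traits[b], eps=eps)
        except DegenerateDyadError:
            if on_degenerate == "raise":
                raise
            skipped.append((a, b))
            continue
        d = compute_descriptors(p)
        rows.append(
            {"id_x": p.id_x, "id_y": p.id_y,
             "z_mu": d.z_mu, "z_an": d.z_an, "z_ag": d.z_ag, "z_al": d.z_al}
        )
        index.append(_dyad_key(a, b))
    if skipped:
        warnings.warn(
            f"{len(skipped)} degenerate dyad(s) excluded: {skipped[:5]}...",
            stacklevel=2,
        )
    out = pd.DataFrame(rows, index=pd.MultiIndex.from_tuples(index, names=["id_a", "id_b"]))
    return out


def _retain_top(values: pd.Series, q: float) -> pd.Index:
    """Indices of the round(q * m) largest values; rank ties broken by
    lexicographic dyad id so retention is deterministic."""
    if not 0 < q <= 1:
        raise ValueError(f"retention fraction must be in (0, 1], got {q}")
    m = len(values)
    k = int(round(q * m))
    order = sorted(values.index, key=lambda idx: (-values[idx], idx))
    return pd.Index(order[:k])


def build_networks(
    traits: pd.Series | dict,
    retention: float | dict = 0.1,
    eps: float = 1e-9,
    on_degenerate: str = "raise",
) -> dict[str, InteractionNetwork]:
    """Build the four descriptor networks from a trait table.

    Parameters
    ----------
    traits
        id -> positive trait value; at least 3 individuals.
    retention
        Edge-retention fraction q in (0, 1], scalar or per-type dict.
        The top q of the n(n-1)/2 descriptor values become edges.
    """
    traits = pd.Series(traits, dtype=float)
    if len(traits) < 3:
        raise ValueError(f"need at least 3 individuals, got {len(traits)}")
    if (traits <= 0).any():
        bad = traits[traits <= 0].index.tolist()
        raise ValueError(f"non-positive trait values for {bad}")
    table = all_pairs_descriptors(traits, eps=eps, on_degenerate=on_degenerate)

    nets = {}
    for net_type, zfield in _DESCRIPTOR_FIELD.items():
        q = retention[net_type] if isinstance(retention, dict) else retention
        vec = table[zfield]
        keep = _retain_top(vec, q)
        g = nx.DiGraph() if net_type in _DIRECTED else nx.Graph()
        g.add_nodes_from((str(i), {"trait": float(traits[i])}) for i in traits.index)
        for key in keep:
            row = table.loc[key]
            # directed edges run larger -> smaller (actor -> recipient)
            g.add_edge(row["id_x"], row["id_y"], weight=float(row[zfield]))
        nets[net_type] = InteractionNetwork(net_type, g, float(q), vec.copy())
    return nets


def assign_mutualism_hierarchy(net: InteractionNetwork, k: float = 1.0) -> RoleAssignment:
    """Leader/follower hierarchy of the mutualism network.

    primary   — hubs: degree > mean + k*sd (strict);
    secondary — non-primary neighbours of a primary;
    tertiary  — nodes adjacent to a secondary (but to no primary) every one
                of whose shortest paths to each reachable primary passes
                through a secondary: the layer directly behind the
                secondaries;
    follower  — remaining nodes adjacent to a tertiary but not to a secondary;
    unassigned — everything else.
    """
    if net.net_type != "mutualism":
        raise ValueError(f"expected a mutualism network, got {net.net_type!r}")
    g = net.graph
    if g.number_of_nodes() == 0:
        raise ValueError("empty network")
    degrees = dict(g.degree())
    vals = np.array(list(degrees.values()), dtype=float)
    cut = vals.mean() + k * vals.std(ddof=0)
    primary = {n for n, d in degrees.items() if d > cut}
    if not primary:
        warnings.warn(
            "no node has degree above mean + k*sd; no primary leaders "
            "(degree distribution too uniform)",
            stacklevel=2,
        )
    secondary = {v for p in primary for v in g.neighbors(p)} - primary

    tertiary = set()
    for node in g.nodes:
        if node in primary or node in secondary:
            continue
        if not any(v in secondary for v in g.neighbors(node)):
            continue
        reachable = [p for p in primary if nx.has_path(g, node, p)]
        if not reachable:
            continue
        blocked = True
        for p in reachable:
            for path in nx.all_shortest_paths(g, node, p):
                if not any(v in secondary for v in path[1:-1]):
                    blocked = False
                    break
            if not blocked:
                break
        if blocked:
            tertiary.add(node)

    follower = {
        n
        for n in g.nodes
        if n not in primary | secondary | tertiary
        and any(v in tertiary for v in g.neighbors(n))
        and not any(v in secondary for v in g.neighbors(n))
    }

    roles = {}
    for n in g.nodes:
        if n in primary:
            roles[n] = "primary_leader"
        elif n in secondary:
            roles[n] = "secondary_leader"
        elif n in tertiary:
            roles[n] = "tertiary_leader"
        elif n in follower:
            roles[n] = "follower"
        else:
            roles[n] = "unassigned"
    return RoleAssignment(net.net_type, roles, graph=g)


def assign_directional_roles(net: InteractionNetwork) -> RoleAssignment:
    """Actor/recipient roles in the aggression or altruism network.

    out-edges only -> hawk (altruist); in-edges only -> dove (egoist);
    both -> mixed role; no edges -> isolated.
    """
    if net.net_type not in _DIRECTED:
        raise ValueError(f"expected aggression or altruism network, got {net.net_type!r}")
    if net.net_type == "aggression":
        actor, mixed, recipient = "hawk", "hawk_dove", "dove"
    else:
        actor, mixed, recipient = "altruist", "altruist_egoist", "egoist"
    g = net.graph
    roles = {}
    for n in g.nodes:
        out_d, in_d = g.out_degree(n), g.in_degree(n)
        if out_d and in_d:
            roles[n] = mixed
        elif out_d:
            roles[n] = actor
        elif in_d:
            roles[n] = recipient
        else:
            roles[n] = "isolated"
    return RoleAssignment(net.net_type, roles, graph=g)


def tier_mass_ratio(
    roles: RoleAssignment,
    traits: pd.Series | dict,
    tier_pair: tuple[str, str],
    threshold: float = PHI,
    alternative: str = "greater",
    n_permutations: int = 0,
    seed: int = 0,
) -> TierRatioResult:
    """Test the mean lower/upper cross-tier trait ratio against a threshold.

    ``tier_pair = (lower_tier_label, upper_tier_label)``.  If the role
    assignment carries a graph, only connected cross-tier dyads enter;
    otherwise all cross-tier pairs do.  The test is a one-sample one-sided
    t-test of the dyad ratios against ``threshold`` (``alternative``
    "greater" or "less").  Dyads sharing an individual are not independence-
    corrected; an optional label-permutation p-value (seeded) is also
    computed when ``n_permutations > 0``.
    """
    traits = pd.Series(traits, dtype=float)
    traits.index = traits.index.map(str)
    lower_label, upper_label = tier_pair
    lower = roles.tier(lower_label)
    upper = roles.tier(upper_label)
    if not lower:
        raise ValueError(f"tier {lower_label!r} is empty")
    if not upper:
        raise ValueError(f"tier {upper_label!r} is empty")
    if alternative not in ("greater", "less"):
        raise ValueError(f"alternative must be 'greater' or 'less', got {alternative!r}")

    def _mean_ratio(lo_nodes, up_nodes, return_ratios=False):
        ratios = []
        for u in up_nodes:
            for l in lo_nodes:
                if l == u:
                    continue
                if roles.graph is not None and not (
                    roles.graph.has_edge(u, l) or roles.graph.has_edge(l, u)
                ):
                    continue
                ratios.append(traits[l] / traits[u])
        arr = np.asarray(ratios, dtype=float)
        return arr if return_ratios else (arr.mean() if len(arr) else np.nan)

    ratios = _mean_ratio(lower, upper, return_ratios=True)
    if len(ratios) == 0:
        raise ValueError(
            f"no connected cross-tier dyads between {lower_label!r} and {upper_label!r}"
        )
    mean_ratio = float(ratios.mean())

    if len(ratios) > 1 and np.ptp(ratios) > 0:
        t_res = stats.ttest_1samp(ratios, popmean=threshold, alternative=alternative)
        statistic, p = float(t_res.statistic), float(t_res.pvalue)
    else:
        # degenerate: a single dyad or zero spread — report the sign directly
        if mean_ratio == threshold:
            statistic, p = 0.0, 0.5
        else:
            above = mean_ratio > threshold
            statistic = np.inf if above else -np.inf
            p = 0.0 if (above == (alternative == "greater")) else 1.0

    p_perm = None
    if n_permutations > 0:
        rng = np.random.default_rng(seed)
        nodes = list(lower) + list(upper)
        n_low = len(lower)
        hits = 0
        for _ in range(n_permutations):
            perm = rng.permutation(nodes)
            m = _mean_ratio(perm[:n_low], perm[n_low:])
            if np.isnan(m):
                continue
            if alternative == "greater":
                hits += m >= mean_ratio
            else:
                hits += m <= mean_ratio
        p_perm = float((hits + 1) / (n_permutations + 1))

    return TierRatioResult(
        net_type=roles.net_type,
        tier_pair=tier_pair,
        ratios=ratios,
        mean_ratio=mean_ratio,
        threshold=float(threshold),
        statistic=statistic,
        p=p,
        direction="above" if mean_ratio > threshold else "below",
        alternative=alternative,
        p_perm=p_perm,
    )


# --- relatedness -----------------------------------------------------------


def validate_genotypes(geno: pd.DataFrame, max_missing: float = 0.5) -> pd.DataFrame:
    """Check a 0/1/2 genotype matrix (individuals x SNPs, NaN = missing)."""
    arr = geno.to_numpy(dtype=float)
    valid = np.isnan(arr) | np.isin(arr, (0.0, 1.0, 2.0))
    if not valid.all():
        bad = np.argwhere(~valid)[0]
        raise ValueError(
            f"genotype codes must be 0/1/2/missing; found {arr[tuple(bad)]!r} at "
            f"individual {geno.index[bad[0]]!r}, SNP {geno.columns[bad[1]]!r}"
        )
    miss = np.isnan(arr).mean(axis=0)
    keep = miss <= max_missing
    if not keep.all():
        warnings.warn(
            f"{(~keep).sum()} SNP(s) exceed the missing-fraction cap "
            f"{max_missing} and were dropped",
            stacklevel=2,
        )
        geno = geno.loc[:, keep]
    return geno


def ibs_matrix(geno: pd.DataFrame) -> pd.DataFrame:
    """Pairwise allele-sharing similarity: mean over non-missing SNPs of
    ``(2 - |g_i - g_j|) / 2``.  1 for identical genotypes, 0 for opposite
    homozygotes at every SNP."""
    arr = geno.to_numpy(dtype=float)
    n = arr.shape[0]
    sim = np.ones((n, n))
    for i in range(n):
        for j in range(i + 1, n):
            diff = np.abs(arr[i] - arr[j])
            ok = ~np.isnan(diff)
            if not ok.any():
                sim[i, j] = sim[j, i] = np.nan
                continue
            sim[i, j] = sim[j, i] = np.mean((2.0 - diff[ok]) / 2.0)
    return pd.DataFrame(sim, index=geno.index.map(str), columns=geno.index.map(str))


def relatedness_network(
    geno: pd.DataFrame, retention: float = 0.1, hub_k: float = 1.0,
    max_missing: float = 0.5,
) -> tuple[InteractionNetwork, RoleAssignment]:
    """Relatedness network from SNP genotypes, with core/periphery roles.

    Pairwise similarity is the IBS fraction; the top ``retention`` fraction
    of dyads become undirected edges; core members are hubs by the same
    degree rule (> mean + hub_k * sd) as primary leaders.
    """
    if len(geno) < 3:
        raise ValueError(f"need at least 3 individuals, got {len(geno)}")
    if geno.shape[1] < 50:
        raise ValueError(f"need at least 50 SNPs, got {geno.shape[1]}")
    geno = validate_genotypes(geno, max_missing=max_missing)
    sim = ibs_matrix(geno)
    ids = list(sim.index)
    pairs, index = [], []
    for a, b in itertools.combinations(sorted(ids), 2):
        v = sim.loc[a, b]
        if np.isnan(v):
            warnings.warn(f"pair ({a!r}, {b!r}) has no shared non-missing SNPs; excluded",
                          stacklevel=2)
            continue
        pairs.append(v)
        index.append(_dyad_key(a, b))
    vec = pd.Series(pairs, index=pd.MultiIndex.from_tuples(index, names=["id_a", "id_b"]))
    keep = _retain_top(vec, retention)
    g = nx.Graph()
    g.add_nodes_from(ids)
    for a, b in keep:
        g.add_edge(a, b, weight=float(vec[(a, b)]))
    net = InteractionNetwork("relatedness", g, float(retention), vec)

    degrees = dict(g.degree())
    vals = np.array(list(degrees.values()), dtype=float)
    cut = vals.mean() + hub_k * vals.std(ddof=0)
    roles = {n: ("core" if d > cut else "periphery") for n, d in degrees.items()}
    return net, RoleAssignment("relatedness", roles, graph=g)


# --- cross-network statistics ----------------------------------------------


def network_correlation(net_a: InteractionNetwork, net_b: InteractionNetwork):
    """Pearson correlation of two networks' all-dyad value vectors.

    Uses the pre-culling vectors so both networks align over the same
    n(n-1)/2 dyads.  Returns (r, p); (nan, nan) with a warning when either
    vector has zero variance.
    """
    joined = pd.concat([net_a.all_pairs, net_b.all_pairs], axis=1, join="inner")
    joined = joined.dropna()
    if len(joined) < 3:
        raise ValueError("fewer than 3 shared dyads between the two networks")
    a, b = joined.iloc[:, 0].to_numpy(), joined.iloc[:, 1].to_numpy()
    if np.ptp(a) == 0 or np.ptp(b) == 0:
        warnings.warn(
            f"zero variance in {net_a.net_type}/{net_b.net_type} dyad values; "
            "correlation undefined",
            stacklevel=2,
        )
        return float("nan"), float("nan")
    r, p = stats.pearsonr(a, b)
    return float(r), float(p)


def network_correlation_matrix(nets: dict[str, InteractionNetwork]) -> pd.DataFrame:
    names = list(nets)
    out = pd.DataFrame(np.eye(len(names)), index=names, columns=names)
    for a, b in itertools.combinations(names, 2):
        r, _ = network_correlation(nets[a], nets[b])
        out.loc[a, b] = out.loc[b, a] = r
    return out


def compare_core_periphery_trait(roles: RoleAssignment, traits: pd.Series | dict):
    """Welch two-sample t-test of trait values, core vs periphery members.

    Returns a dict with the statistic, two-sided p, and group means.
    """
    traits = pd.Series(traits, dtype=float)
    traits.index = traits.index.map(str)
    core = [traits[n] for n in roles.tier("core")]
    peri = [traits[n] for n in roles.tier("periphery")]
    if len(core) < 2 or len(peri) < 2:
        raise ValueError(
            f"both groups need >= 2 members; core={len(core)}, periphery={len(peri)}"
        )
    res = stats.ttest_ind(core, peri, equal_var=False)
    return {
        "statistic": float(res.statistic),
        "p": float(res.pvalue),
        "mean_core": float(np.mean(core)),
        "mean_periphery": float(np.mean(peri)),
        "n_core": len(core),
        "n_periphery": len(peri),
    }
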