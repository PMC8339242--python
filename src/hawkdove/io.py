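"""Readers, writers, run configuration and the end-to-end pipeline.

Canonical dialects: CSV/TSV with explicit headers for tables, edge-list CSV
plus GraphML for networks, JSON for scalar results.  Every run writes a
manifest (inputs, config, seed, package version) sufficient to reproduce it.
"""

from __future__ import annotations

import hashlib
import json
import warnings
from dataclasses import asdict, dataclass, field
from pathlib import Path

import networkx as nx
import numpy as np
import pandas as pd
import yaml

from . import __version__
from .decision import FIB_MARK, PHI, thresholds
from .networks import (
    assign_directional_roles,
    assign_mutualism_hierarchy,
    build_networks,
    compare_core_periphery_trait,
    network_correlation_matrix,
    relatedness_network,
    tier_mass_ratio,
)
from .validation import CocultureStudy


class SchemaError(ValueError):
    """An input file violates the expected schema."""


# --- readers ---------------------------------------------------------------


def _read_table(path) -> pd.DataFrame:
    path = Path(path)
    sep = "\t" if path.suffix.lower() in (".tsv", ".txt") else ","
    try:
        return pd.read_csv(path, sep=sep)
    except Exception as e:
        raise SchemaError(f"could not parse {path}: {e}") from e


def read_traits(path) -> pd.Series:
    """Trait table (columns: id, trait) -> Series indexed by id."""
    df = _read_table(path)
    missing = {"id", "trait"} - set(df.columns)
    if missing:
        raise SchemaError(f"{path}: missing column(s) {sorted(missing)}")
    for i, v in enumerate(df["trait"]):
        try:
            fv = float(v)
        except (TypeError, ValueError):
            raise SchemaError(f"{path}: non-numeric trait {v!r} at data line {i + 2}")
        if not fv > 0:
            raise SchemaError(f"{path}: non-positive trait {v!r} at data line {i + 2}")
    if df["id"].duplicated().any():
        dup = df.loc[df["id"].duplicated(), "id"].iloc[0]
        raise SchemaError(f"{path}: duplicate individual id {dup!r}")
    return pd.Series(df["trait"].astype(float).values, index=df["id"].astype(str), name="trait")


def read_abundances(path) -> pd.DataFrame:
    """Long-format abundance table; validates schema and per-series times."""
    df = _read_table(path)
    required = ["pair_id", "strain_id", "condition", "time", "abundance"]
    missing = set(required) - set(df.columns)
    if missing:
        raise SchemaError(f"{path}: missing column(s) {sorted(missing)}")
    bad_cond = set(df["condition"].unique()) - {"monoculture", "coculture"}
    if bad_cond:
        raise SchemaError(f"{path}: unknown condition value(s) {sorted(bad_cond)}")
    if (df["abundance"].astype(float) <= 0).any():
        row = df.index[df["abundance"].astype(float) <= 0][0]
        raise SchemaError(f"{path}: non-positive abundance at data line {row + 2}")
    for key, sub in df.groupby(["pair_id", "strain_id", "condition"]):
        t = sub["time"].to_numpy(float)
        if np.any(np.diff(t) <= 0):
            raise SchemaError(f"{path}: non-monotone times for series {key}")
    return df


def read_genotypes(path) -> pd.DataFrame:
    """Genotype TSV (rows: individuals, columns: SNPs; codes 0/1/2, blank = missing)."""
    df = pd.read_csv(path, sep="\t", index_col=0)
    arr = df.to_numpy()
    try:
        arr = arr.astype(float)
    except ValueError as e:
        raise SchemaError(f"{path}: non-numeric genotype code ({e})") from e
    ok = np.isnan(arr) | np.isin(arr, (0.0, 1.0, 2.0))
    if not ok.all():
        i, j = np.argwhere(~ok)[0]
        raise SchemaError(
            f"{path}: invalid genotype code {arr[i, j]!r} for individual "
            f"{df.index[i]!r}, SNP {df.columns[j]!r}"
        )
    return pd.DataFrame(arr, index=df.index.map(str), columns=df.columns)


def read_genotypes_vcf(path) -> pd.DataFrame:
    """Biallelic GT dosages from a VCF; multiallelic sites skipped with a warning."""
    try:
        from cyvcf2 import VCF
    except ImportError as e:  # pragma: no cover - optional dependency
        raise ImportError("reading VCF requires the optional cyvcf2 dependency") from e
    vcf = VCF(str(path))
    samples = list(vcf.samples)
    cols, names = [], []
    for var in vcf:
        if len(var.ALT) != 1:
            warnings.warn(f"{path}: multiallelic site {var.CHROM}:{var.POS} skipped",
                          stacklevel=2)
            continue
        # gt_types: 0=hom-ref, 1=het, 2=hom-alt, 3=unknown
        g = np.asarray(var.gt_types, dtype=float)
        g[g == 3] = np.nan
        cols.append(g)
        names.append(f"{var.CHROM}:{var.POS}")
    if not cols:
        raise SchemaError(f"{path}: no usable biallelic sites")
    return pd.DataFrame(np.column_stack(cols), index=samples, columns=names)


# --- writers ---------------------------------------------------------------


def write_network(net, out_prefix: Path):
    """Edge-list CSV + GraphML for one network."""
    net.edge_frame().to_csv(f"{out_prefix}.edges.csv", index=False)
    nx.write_graphml(net.graph, f"{out_prefix}.graphml")


def _jsonable(obj):
    if isinstance(obj, (np.floating, np.integer)):
        return obj.item()
    if isinstance(obj, np.ndarray):
        return obj.tolist()
    if isinstance(obj, tuple):
        return list(obj)
    raise TypeError(f"not JSON serializable: {type(obj)}")


def write_json(obj, path):
    Path(path).write_text(json.dumps(obj, indent=2, default=_jsonable) + "\n")


# --- configuration and pipeline --------------------------------------------


@dataclass
class RunConfig:
    """Configuration of one end-to-end run."""

    traits_path: str | None = None
    abundances_path: str | None = None
    genotypes_path: str | None = None
    out_dir: str = "hawkdove_out"
    retention: float = 0.1
    hub_k: float = 1.0
    phase_cutoff: float = 0.95
    correlation: str = "pearson"
    eps: float = 1e-9
    seed: int = 0
    ordering: str = "per_time"
    tier_tests: tuple = field(
        default_factory=lambda: (
            # (network, lower tier, upper tier, threshold name, alternative)
            ("mutualism", "secondary_leader", "primary_leader", "phi", "greater"),
            ("aggression", "hawk_dove", "hawk", "phi", "less"),
            ("aggression", "dove", "hawk_dove", "phi", "less"),
            ("altruism", "altruist_egoist", "altruist", "fib_mark", "greater"),
            ("altruism", "egoist", "altruist_egoist", "fib_mark", "greater"),
        )
    )

    def __post_init__(self):
        if not 0 < self.retention <= 1:
            raise ValueError(f"retention must be in (0, 1], got {self.retention}")
        if not 0 < self.phase_cutoff <= 1:
            raise ValueError(f"phase_cutoff must be in (0, 1], got {self.phase_cutoff}")

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        data = yaml.safe_load(Path(path).read_text()) or {}
        known = {f for f in cls.__dataclass_fields__}
        unknown = set(data) - known
        if unknown:
            raise SchemaError(f"{path}: unknown config key(s) {sorted(unknown)}")
        if "tier_tests" in data:
            data["tier_tests"] = tuple(tuple(t) for t in data["tier_tests"])
        return cls(**data)

    def digest(self) -> str:
        return hashlib.sha256(
            json.dumps(asdict(self), sort_keys=True, default=_jsonable).encode()
        ).hexdigest()[:16]


class PipelineError(RuntimeError):
    def __init__(self, stage, cause):
        self.stage = stage
        super().__init__(f"pipeline stage {stage!r} failed: {cause}")


_THRESHOLD_BY_NAME = {"phi": PHI, "fib_mark": FIB_MARK}


def run_pipeline(config: RunConfig) -> dict:
    """Execute every arm the configured inputs allow and write all outputs.

    Fish arm (traits): descriptors -> networks -> roles -> tier-ratio tests;
    plus the relatedness network if genotypes are given.  Co-culture arm
    (abundances): growth fits -> strengths -> per-phase correlations.
    Returns the result bundle; everything is also written under
    ``config.out_dir`` together with a manifest.
    """
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    bundle: dict = {"thresholds": thresholds().as_dict()}

    if config.traits_path:
        stage = "traits"
        try:
            traits = read_traits(config.traits_path)
            stage = "networks"
            nets = build_networks(traits, retention=config.retention, eps=config.eps,
                                  on_degenerate="skip")
            roles = {"mutualism": assign_mutualism_hierarchy(nets["mutualism"], k=config.hub_k)}
            for t in ("aggression", "altruism"):
                roles[t] = assign_directional_roles(nets[t])

            stage = "tier_tests"
            tier_results = []
            for net_type, low, up, th_name, alt in config.tier_tests:
                try:
                    res = tier_mass_ratio(
                        roles[net_type], traits, (low, up),
                        threshold=_THRESHOLD_BY_NAME[th_name], alternative=alt,
                        seed=config.seed,
                    )
                except ValueError as e:
                    tier_results.append({"network": net_type, "tiers": f"{low}/{up}",
                                         "skipped": str(e)})
                    continue
                tier_results.append(
                    {"network": net_type, "tiers": f"{low}/{up}",
                     "threshold": res.threshold, "mean_ratio": res.mean_ratio,
                     "n_dyads": len(res.ratios), "statistic": res.statistic,
                     "p": res.p, "direction": res.direction, "alternative": alt}
                )

            stage = "genotypes"
            if config.genotypes_path:
                geno = read_genotypes(config.genotypes_path)
                rel_net, rel_roles = relatedness_network(
                    geno, retention=config.retention, hub_k=config.hub_k
                )
                nets["relatedness"] = rel_net
                roles["relatedness"] = rel_roles
                bundle["core_periphery"] = compare_core_periphery_trait(rel_roles, traits)

            stage = "network_correlations"
            corr = network_correlation_matrix(nets)

            for name, net in nets.items():
                write_network(net, out / f"network_{name}")
            role_frame = pd.concat([r.to_frame() for r in roles.values()], ignore_index=True)
            role_frame.to_csv(out / "roles.csv", index=False)
            corr.to_csv(out / "network_correlations.csv")
            write_json(tier_results, out / "tier_tests.json")
            bundle.update(networks=nets, roles=roles, tier_tests=tier_results,
                          network_correlations=corr)
        except (SchemaError, ValueError, KeyError) as e:
            raise PipelineError(stage, e) from e

    if config.abundances_path:
        stage = "abundances"
        try:
            frame = read_abundances(config.abundances_path)
            stage = "coculture_validation"
            study = CocultureStudy(frame, ordering=config.ordering,
                                   phase_cutoff=config.phase_cutoff)
            res = study.fit(method=config.correlation, seed=config.seed)
            res.table.to_csv(out / "strengths.csv", index=False)
            res.correlations.to_csv(out / "phase_correlations.csv", index=False)
            res.fits.to_csv(out / "growth_fits.csv", index=False)
            bundle["coculture"] = res
        except (SchemaError, ValueError) as e:
            raise PipelineError(stage, e) from e

    manifest = {
        "package": "hawkdove",
        "version": __version__,
        "seed": config.seed,
        "config": asdict(config),
        "config_digest": config.digest(),
        "inputs": {
            k: v for k, v in (
                ("traits", config.traits_path),
                ("abundances", config.abundances_path),
                ("genotypes", config.genotypes_path),
            ) if v
        },
        "thresholds": bundle["thresholds"],
    }
    write_json(manifest, out / "manifest.json")
    bundle["manifest"] = manifest
    return bundle
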