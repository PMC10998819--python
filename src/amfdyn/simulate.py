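"""Synthetic year-round paired root/soil AMF community datasets.

Emulates a two-forest bimonthly sampling campaign: at each site the same
trees are sampled every two months over a full year, and every tree
contributes a paired root and soil sample.  The community model is a
fixed baseline composition (a few highly abundant persistent OTUs, many
rare ones) perturbed per sample on the log scale by

* a compartment offset for root- or soil-preferential OTUs,
* a soil-pH response for designated pH-responsive OTUs,
* structural zeros for seasonal OTUs in their absence months,

renormalized, and then drawn as Dirichlet-multinomial counts at a
per-sample read depth sampled uniformly from the configured range.
Structural (not sampling) zeros are used for seasonality so persistence
classification has unambiguous ground truth.

Soil chemistry (pH, total C, total N, total P) is drawn per sample from
positive-truncated normals around per-site-per-month means/SDs; the
defaults reproduce the published field measurements of the two
*Cryptomeria japonica* plantations the design mimics.  pH is drawn
first because the community model depends on it.
"""

from __future__ import annotations

import dataclasses
import json
import tomllib
from pathlib import Path

import numpy as np
import pandas as pd

from .io import (
    COMPARTMENTS,
    MONTH_ORDER,
    DesignError,
    OtuCountTable,
    write_count_table,
    write_metadata,
    write_text_atomic,
)

SITE_NAMES: tuple[str, str] = ("UTCBF", "UTCF")

#: The 24 yearlong cross-site average relative abundances of the dominant
#: OTUs in the field study, sorted descending; used as default targets.
DOMINANT_PROPS: tuple[float, ...] = (
    0.184, 0.177, 0.046, 0.042, 0.038, 0.033, 0.032, 0.028,
    0.027, 0.027, 0.025, 0.023, 0.018, 0.017, 0.017, 0.015,
    0.014, 0.014, 0.012, 0.011, 0.011, 0.010, 0.010, 0.009,
)

#: Published per-site-per-month soil chemistry (mean, SD):
#: (pH, TC %, TN %, TP mg/kg).
SOIL_PARAMS: dict[tuple[str, str], tuple[float, ...]] = {
    ("UTCBF", "May"): (4.74, 0.47, 10.29, 4.84, 0.65, 0.26, 81.43, 25.03),
    ("UTCBF", "July"): (5.02, 0.24, 10.07, 1.95, 0.61, 0.10, 76.33, 18.03),
    ("UTCBF", "September"): (4.61, 0.45, 6.29, 2.57, 0.45, 0.15, 59.30, 18.65),
    ("UTCBF", "November"): (5.23, 0.39, 8.44, 3.65, 0.55, 0.19, 89.58, 18.42),
    ("UTCBF", "January"): (5.10, 0.53, 9.45, 3.67, 0.74, 0.29, 31.33, 9.40),
    ("UTCBF", "March"): (5.43, 0.37, 7.14, 2.85, 0.48, 0.16, 28.86, 8.54),
    ("UTCF", "May"): (4.78, 0.33, 16.84, 3.41, 1.06, 0.18, 81.19, 9.85),
    ("UTCF", "November"): (5.29, 0.40, 17.70, 3.18, 1.06, 0.15, 69.19, 5.15),
    ("UTCF", "March"): (5.09, 0.23, 16.48, 2.01, 1.01, 0.11, 70.62, 6.62),
}

SOIL_COLUMNS = (
    "pH_mean", "pH_sd", "TC_mean", "TC_sd",
    "TN_mean", "TN_sd", "TP_mean", "TP_sd",
)

#: Genus pool for synthetic taxonomy hits, weighted toward Glomus as in
#: Glomeraceae-dominated conifer plantations.
HIT_GENERA = (
    ("Glomus", 0.80), ("Acaulospora", 0.05), ("Diversispora", 0.04),
    ("Archaeospora", 0.03), ("Rhizophagus", 0.03), ("Scutellospora", 0.02),
    ("Gigaspora", 0.01), ("Entrophospora", 0.01), ("Paraglomus", 0.01),
)

UNCULTURED_TITLE = "uncultured Glomeromycotina"


def default_soil_params(
    site_names: tuple[str, ...], months: tuple[str, ...]
) -> pd.DataFrame:
    """Published chemistry parameters, with gaps filled per site.

    The second site was only measured in three months; its missing
    months fall back to the per-variable mean of its measured rows.
    Extra sites reuse the first site's parameters.
    """
    rows = []
    for site in site_names:
        source = site if site in SITE_NAMES else SITE_NAMES[0]
        measured = [v for (s, _), v in SOIL_PARAMS.items() if s == source]
        fallback = tuple(np.mean(measured, axis=0))
        for month in months:
            params = SOIL_PARAMS.get((source, month), fallback)
            rows.append({"site": site, "month": month,
                         **dict(zip(SOIL_COLUMNS, params))})
    return pd.DataFrame(rows)


@dataclasses.dataclass
class SimulationConfig:
    """Knobs of the study-design simulator.

    Defaults reproduce the field campaign's scale: 2 sites x 5 trees x
    6 bimonthly months x paired root+soil = 120 samples (90 when the
    second site is pruned to 3 months via :func:`paper_design`), ~700
    OTUs led by two OTUs near 18%, read depths on the published
    3537-16435 range.
    """

    seed: int = 0
    n_sites: int = 2
    n_trees_per_site: int = 5
    months: tuple[str, ...] = MONTH_ORDER
    site_months: dict[str, tuple[str, ...]] | None = None
    compartments: tuple[str, str] = COMPARTMENTS
    n_otus: int = 700
    n_dominant: int = 24
    dominant_mean_props: tuple[float, ...] = DOMINANT_PROPS
    rare_decay: float = 0.5  # tail proportions fall off as (rank)^-rare_decay
    n_seasonal: int = 30
    seasonal_absence_months: dict[int, frozenset[str]] | None = None
    n_compartment_preferential: int = 60
    compartment_effect: float = 1.0  # log-fold root-vs-soil offset
    n_ph_responsive: int = 4
    ph_slope: float = 1.0  # per-unit-pH log-abundance slope
    ph_responsive_otus: tuple[int, ...] | None = None
    depth_range: tuple[int, int] = (3537, 16435)
    overdispersion: float = 200.0  # Dirichlet concentration; inf = multinomial
    soil_param_table: pd.DataFrame | None = None
    dominance_threshold: float = 0.01
    fraction_below: float = 26 / 698  # hit-table rows failing the 95% rule
    fraction_uncultured: float = 75 / 698
    site_names: tuple[str, ...] | None = None

    # -- derived design (filled by validate) --------------------------------

    def resolved_site_names(self) -> tuple[str, ...]:
        if self.site_names is not None:
            return tuple(self.site_names)
        names = list(SITE_NAMES[: self.n_sites])
        while len(names) < self.n_sites:
            names.append(f"Site{len(names) + 1}")
        return tuple(names)

    def months_for_site(self, site: str) -> tuple[str, ...]:
        if self.site_months and site in self.site_months:
            return tuple(self.site_months[site])
        return tuple(self.months)

    def otu_ids(self) -> list[str]:
        return [f"OTU{i + 1:04d}" for i in range(self.n_otus)]

    def resolved_soil_params(self) -> pd.DataFrame:
        if self.soil_param_table is not None:
            return self.soil_param_table
        return default_soil_params(self.resolved_site_names(), tuple(self.months))

    def seasonal_assignments(self) -> dict[int, frozenset[str]]:
        """Seasonal OTU -> absence-month set (defaults cycle the calendar)."""
        if self.seasonal_absence_months is not None:
            return {int(k): frozenset(v) for k, v in self.seasonal_absence_months.items()}
        months = list(self.months)
        out: dict[int, frozenset[str]] = {}
        for j in range(self.n_seasonal):
            idx = self.n_dominant + j
            absent = {months[j % len(months)]}
            if j % 3 == 0:  # a third of seasonal OTUs miss two months
                absent.add(months[(j + 2) % len(months)])
            out[idx] = frozenset(absent)
        return out

    def compartment_effects(self) -> np.ndarray:
        """Signed per-OTU log-fold offsets applied in root samples."""
        eff = np.zeros(self.n_otus)
        if self.compartment_effect == 0 or self.n_compartment_preferential == 0:
            return eff
        # mid-rank dominants in balanced +/- pairs (top-2 and the
        # threshold-adjacent tail dominants stay neutral), then rare-tail OTUs
        chosen = [i for i in range(2, min(12, self.n_dominant, self.n_otus))]
        chosen = chosen[: self.n_compartment_preferential]
        k = self.n_dominant + self.n_seasonal
        while len(chosen) < self.n_compartment_preferential and k < self.n_otus:
            chosen.append(k)
            k += 1
        for pos, idx in enumerate(chosen):
            eff[idx] = self.compartment_effect * (1 if pos % 2 == 0 else -1)
        return eff

    def ph_slopes(self) -> np.ndarray:
        """Signed per-OTU pH slopes (alternating response directions)."""
        slopes = np.zeros(self.n_otus)
        if self.ph_slope == 0 or self.n_ph_responsive == 0:
            return slopes
        if self.ph_responsive_otus is not None:
            chosen = list(self.ph_responsive_otus)
        else:
            pool = [0, 1, 2, 6]  # mirrors the four strongly pH-correlated OTUs
            chosen = pool[: self.n_ph_responsive]
            k = self.n_dominant
            while len(chosen) < self.n_ph_responsive:
                chosen.append(k)
                k += 1
        for pos, idx in enumerate(chosen):
            slopes[idx] = self.ph_slope * (1 if pos % 2 == 0 else -1)
        return slopes

    def baseline_proportions(self) -> np.ndarray:
        """Exact baseline composition: dominants + power-law rare tail."""
        props = np.asarray(self.dominant_mean_props, dtype=float)
        n_tail = self.n_otus - self.n_dominant
        remaining = 1.0 - props.sum()
        tail = np.arange(1, n_tail + 1, dtype=float) ** (-self.rare_decay)
        tail *= remaining / tail.sum()
        return np.concatenate([props, tail])

    def validate(self) -> None:
        props = np.asarray(self.dominant_mean_props, dtype=float)
        if len(props) != self.n_dominant:
            raise DesignError(
                f"dominant_mean_props has {len(props)} entries, expected n_dominant={self.n_dominant}"
            )
        if (props <= 0).any():
            raise DesignError("dominant_mean_props entries must be > 0")
        if props.sum() >= 1:
            raise DesignError("dominant_mean_props must sum to < 1")
        lo, hi = self.depth_range
        if lo < 1 or lo > hi:
            raise DesignError(f"invalid depth_range {self.depth_range}")
        if self.n_dominant + self.n_seasonal > self.n_otus:
            raise DesignError("n_dominant + n_seasonal exceeds n_otus")
        for idx, absent in self.seasonal_assignments().items():
            if not (0 <= idx < self.n_otus):
                raise DesignError(f"seasonal OTU index {idx} out of range")
            unknown = absent - set(self.months)
            if unknown:
                raise DesignError(f"unknown absence months {sorted(unknown)} for OTU {idx}")
        # every sampled month must retain at least one OTU after forced zeros
        assignments = self.seasonal_assignments()
        for month in self.months:
            forced = sum(1 for absent in assignments.values() if month in absent)
            if self.n_otus - forced < 1:
                raise DesignError(f"month {month} would have no nonzero OTU")
        if self.overdispersion <= 0:
            raise DesignError("overdispersion must be > 0 (use inf for multinomial)")

    # -- (de)serialisation ---------------------------------------------------

    def to_dict(self) -> dict:
        d = dataclasses.asdict(self)
        if self.soil_param_table is not None:
            d["soil_param_table"] = self.soil_param_table.to_dict("records")
        if self.seasonal_absence_months is not None:
            d["seasonal_absence_months"] = {
                str(k): sorted(v) for k, v in self.seasonal_absence_months.items()
            }
        return d

    @classmethod
    def from_dict(cls, d: dict) -> "SimulationConfig":
        d = dict(d)
        if d.get("soil_param_table") is not None:
            d["soil_param_table"] = pd.DataFrame(d["soil_param_table"])
        if d.get("seasonal_absence_months") is not None:
            d["seasonal_absence_months"] = {
                int(k): frozenset(v) for k, v in d["seasonal_absence_months"].items()
            }
        for key in ("months", "compartments", "dominant_mean_props",
                    "depth_range", "ph_responsive_otus", "site_names"):
            if d.get(key) is not None:
                d[key] = tuple(d[key])
        if d.get("site_months") is not None:
            d["site_months"] = {k: tuple(v) for k, v in d["site_months"].items()}
        return cls(**d)

    @classmethod
    def from_file(cls, path: str | Path) -> "SimulationConfig":
        path = Path(path)
        if path.suffix == ".toml":
            d = tomllib.loads(path.read_text())
        else:
            d = json.loads(path.read_text())
        return cls.from_dict(d)


def paper_design(seed: int = 0, **overrides) -> SimulationConfig:
    """The 90-sample field design: 6 months at UTCBF, 3 at UTCF."""
    cfg = SimulationConfig(
        seed=seed,
        site_months={"UTCF": ("May", "November", "March")},
        **overrides,
    )
    return cfg


@dataclasses.dataclass
class TruthLabels:
    """Ground-truth per-OTU structure the generator baked in.

    ``dominant`` holds True/False where the expected per-site mean
    abundance clears (or misses) the 1% rule with margin, and ``None``
    for OTUs inside the boundary band where sampling noise makes the
    structural label ambiguous.
    """

    otu_ids: list[str]
    target_prop: np.ndarray
    dominant: list[bool | None]
    seasonal: np.ndarray
    absence_months: dict[str, list[str]]
    ph_responsive: np.ndarray
    ph_slope_signed: np.ndarray
    compartment_preferential: np.ndarray
    compartment_log_effect: np.ndarray
    expected_site_means: pd.DataFrame  # OTU x site

    def to_json(self) -> str:
        return json.dumps(
            {
                "otu_ids": self.otu_ids,
                "target_prop": self.target_prop.tolist(),
                "dominant": self.dominant,
                "seasonal": self.seasonal.astype(bool).tolist(),
                "absence_months": self.absence_months,
                "ph_responsive": self.ph_responsive.astype(bool).tolist(),
                "ph_slope_signed": self.ph_slope_signed.tolist(),
                "compartment_preferential": self.compartment_preferential.astype(bool).tolist(),
                "compartment_log_effect": self.compartment_log_effect.tolist(),
                "expected_site_means": self.expected_site_means.to_dict("list"),
            },
            indent=1,
        )


@dataclasses.dataclass
class SimulatedDataset:
    counts: OtuCountTable
    metadata: pd.DataFrame  # indexed by sample_id, incl. chemistry columns
    chemistry: pd.DataFrame
    truth: TruthLabels
    config: SimulationConfig


def build_metadata(config: SimulationConfig) -> pd.DataFrame:
    """Sample grid: one root and one soil sample per tree per month."""
    rows = []
    for site in config.resolved_site_names():
        for month in config.months_for_site(site):
            for t in range(1, config.n_trees_per_site + 1):
                for comp in config.compartments:
                    rows.append(
                        {
                            "sample_id": f"{site}-T{t}-{month}-{comp}",
                            "site": site,
                            "tree": f"T{t}",
                            "month": month,
                            "compartment": comp,
                        }
                    )
    df = pd.DataFrame(rows).set_index("sample_id")
    df["month"] = pd.Categorical(df["month"], categories=list(config.months), ordered=True)
    return df


def truncated_normal(rng: np.random.Generator, mean: float, sd: float, size: int) -> np.ndarray:
    """Normal(mean, sd) truncated to positive values (mean must be > 0)."""
    if mean <= 0:
        raise DesignError(f"truncated-normal mean must be > 0, got {mean}")
    if sd < 0:
        raise DesignError("sd must be >= 0")
    if sd == 0:
        return np.full(size, float(mean))
    out = rng.normal(mean, sd, size)
    for _ in range(100):
        bad = out <= 0
        if not bad.any():
            return out
        out[bad] = rng.normal(mean, sd, bad.sum())
    raise DesignError(f"truncation failed for mean={mean}, sd={sd}")


def _sample_rng(seed: int, stream: int, index: int) -> np.random.Generator:
    # sub-streams keyed by (stream, sample index) for partial regeneration
    return np.random.Generator(np.random.PCG64(np.random.SeedSequence(seed, spawn_key=(stream, index))))


def generate_soil_chemistry(config: SimulationConfig, metadata: pd.DataFrame) -> pd.DataFrame:
    """Per-sample pH/TC/TN/TP draws (C/N is derived downstream)."""
    params = config.resolved_soil_params().set_index(["site", "month"])
    rows = []
    for i, (sample_id, rec) in enumerate(metadata.iterrows()):
        key = (rec["site"], str(rec["month"]))
        if key not in params.index:
            raise DesignError(f"no soil parameters for site x month {key}")
        p = params.loc[key]
        rng = _sample_rng(config.seed, 1, i)
        rows.append(
            {
                "sample_id": sample_id,
                "pH": truncated_normal(rng, p["pH_mean"], p["pH_sd"], 1)[0],
                "TC": truncated_normal(rng, p["TC_mean"], p["TC_sd"], 1)[0],
                "TN": truncated_normal(rng, p["TN_mean"], p["TN_sd"], 1)[0],
                "TP": truncated_normal(rng, p["TP_mean"], p["TP_sd"], 1)[0],
            }
        )
    return pd.DataFrame(rows).set_index("sample_id")


def _site_mean_ph(config: SimulationConfig, site: str) -> float:
    params = config.resolved_soil_params().set_index(["site", "month"])
    months = config.months_for_site(site)
    return float(np.mean([params.loc[(site, m), "pH_mean"] for m in months]))


def expected_proportions(
    config: SimulationConfig, site: str, month: str, compartment: str, ph: float
) -> np.ndarray:
    """Exact expected composition of one sample under the model."""
    logp = np.log(config.baseline_proportions())
    if compartment == "root":
        logp = logp + config.compartment_effects()
    logp = logp + config.ph_slopes() * (ph - _site_mean_ph(config, site))
    p = np.exp(logp - logp.max())
    for idx, absent in config.seasonal_assignments().items():
        if month in absent:
            p[idx] = 0.0
    total = p.sum()
    if total <= 0:
        raise DesignError(f"no nonzero OTU left in month {month}")
    return p / total


def expected_group_compositions(config: SimulationConfig) -> pd.DataFrame:
    """Expected composition per (site, month, compartment) at mean pH."""
    rows = {}
    for site in config.resolved_site_names():
        params = config.resolved_soil_params().set_index(["site", "month"])
        for month in config.months_for_site(site):
            ph = float(params.loc[(site, month), "pH_mean"])
            for comp in config.compartments:
                rows[(site, month, comp)] = expected_proportions(config, site, month, comp, ph)
    df = pd.DataFrame.from_dict(rows, orient="index", columns=config.otu_ids())
    df.index = pd.MultiIndex.from_tuples(df.index, names=["site", "month", "compartment"])
    return df


def _truth_labels(config: SimulationConfig) -> TruthLabels:
    otu_ids = config.otu_ids()
    groups = expected_group_compositions(config)
    site_means = groups.groupby(level="site", observed=True).mean().T  # OTU x site
    min_site = site_means.min(axis=1).to_numpy()
    thr = config.dominance_threshold
    dominant: list[bool | None] = []
    for m in min_site:
        if m >= 1.5 * thr:
            dominant.append(True)
        elif m < 0.8 * thr:
            dominant.append(False)
        else:
            dominant.append(None)  # boundary band: no unambiguous truth
    assignments = config.seasonal_assignments()
    seasonal = np.zeros(config.n_otus, dtype=bool)
    absence = {}
    for idx, months in assignments.items():
        seasonal[idx] = True
        absence[otu_ids[idx]] = sorted(months, key=list(config.months).index)
    slopes = config.ph_slopes()
    eff = config.compartment_effects()
    return TruthLabels(
        otu_ids=otu_ids,
        target_prop=config.baseline_proportions(),
        dominant=dominant,
        seasonal=seasonal,
        absence_months=absence,
        ph_responsive=slopes != 0,
        ph_slope_signed=slopes,
        compartment_preferential=eff != 0,
        compartment_log_effect=eff,
        expected_site_means=site_means,
    )


def generate_dataset(config: SimulationConfig) -> SimulatedDataset:
    """Draw a full dataset (metadata, chemistry, counts, truth labels).

    Identical config (including seed) always yields identical output:
    every sample has its own PRNG sub-stream keyed by sample index.
    """
    config.validate()
    metadata = build_metadata(config)
    chemistry = generate_soil_chemistry(config, metadata)
    chemistry["CN"] = chemistry["TC"] / chemistry["TN"]

    assignments = config.seasonal_assignments()
    lo, hi = config.depth_range
    theta = config.overdispersion
    counts = np.zeros((len(metadata), config.n_otus), dtype=np.int64)
    for i, (sample_id, rec) in enumerate(metadata.iterrows()):
        rng = _sample_rng(config.seed, 2, i)
        depth = int(rng.integers(lo, hi + 1))
        p = expected_proportions(
            config, rec["site"], str(rec["month"]), rec["compartment"],
            chemistry.loc[sample_id, "pH"],
        )
        nz = p > 0
        if np.isinf(theta):
            q = p[nz]
        else:
            gamma = rng.standard_gamma(p[nz] * theta)
            total = gamma.sum()
            if total <= 0:  # pathological underflow; fall back to expectation
                q = p[nz]
            else:
                q = gamma / total
        counts[i, nz] = rng.multinomial(depth, q / q.sum())
    table = OtuCountTable(
        pd.DataFrame(counts, index=metadata.index, columns=config.otu_ids())
    )
    truth = _truth_labels(config)
    meta_full = metadata.join(chemistry)
    return SimulatedDataset(
        counts=table, metadata=meta_full, chemistry=chemistry, truth=truth, config=config
    )


def generate_hit_table(
    truth: TruthLabels,
    config: SimulationConfig,
    fraction_below: float | None = None,
    fraction_uncultured: float | None = None,
) -> pd.DataFrame:
    """Synthetic BLAST-tabular rows exercising the taxonomy decision rule.

    Each OTU gets a best hit that is either below the 95% thresholds
    (``fraction_below`` of OTUs), an "uncultured Glomeromycotina" match,
    or a genus-labelled match; qualifying OTUs also get a weaker decoy
    hit so best-hit selection is exercised.
    """
    f_below = config.fraction_below if fraction_below is None else fraction_below
    f_unc = config.fraction_uncultured if fraction_uncultured is None else fraction_uncultured
    rng = np.random.Generator(np.random.PCG64(np.random.SeedSequence(config.seed, spawn_key=(3,))))
    genera, weights = zip(*HIT_GENERA)
    weights = np.asarray(weights) / np.sum(weights)
    rows = []
    for otu in truth.otu_ids:
        u = rng.random()
        if u < f_below:
            pid = round(rng.uniform(80.0, 94.9), 2)
            cov = round(rng.uniform(80.0, 94.9), 2)
            title = UNCULTURED_TITLE if rng.random() < f_unc else (
                f"{rng.choice(genera, p=weights)} sp."
            )
            rows.append((otu, f"VTX{rng.integers(1, 99999):05d}", pid, cov, title))
            continue
        uncultured = rng.random() < f_unc
        pid = round(rng.uniform(95.5, 100.0), 2)
        cov = round(rng.uniform(95.5, 100.0), 2)
        vtx = f"VTX{rng.integers(1, 99999):05d}"
        if uncultured:
            rows.append((otu, f"UNC{rng.integers(1, 99999):05d}", pid, cov, UNCULTURED_TITLE))
        else:
            genus = rng.choice(genera, p=weights)
            rows.append((otu, vtx, pid, cov, f"{genus} {vtx}"))
        if rng.random() < 0.5:  # weaker decoy hit exercising best-hit choice
            lo2, hi2 = (80.0, 94.9) if f_below > 0 else (95.0, min(pid, cov))
            pid2 = round(rng.uniform(lo2, hi2), 2)
            cov2 = round(rng.uniform(lo2, hi2), 2)
            title2 = UNCULTURED_TITLE if rng.random() < f_unc else (
                f"{rng.choice(genera, p=weights)} sp."
            )
            rows.append((otu, f"VTX{rng.integers(1, 99999):05d}", pid2, cov2, title2))
    return pd.DataFrame(rows, columns=["qseqid", "sseqid", "pident", "qcovs", "stitle"])


def write_dataset(dataset: SimulatedDataset, outdir: str | Path, hits: pd.DataFrame | None = None) -> None:
    """Write counts/metadata/chemistry/truth (and optionally hits) TSV/JSON."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    write_count_table(dataset.counts, outdir / "counts.tsv")
    meta = dataset.metadata[["site", "tree", "month", "compartment"]]
    write_metadata(meta, outdir / "metadata.tsv")
    chem = dataset.chemistry[["pH", "TC", "TN", "TP"]].round(6)
    write_text_atomic(outdir / "chemistry.tsv", chem.to_csv(sep="\t", lineterminator="\n"))
    write_text_atomic(outdir / "truth.json", dataset.truth.to_json())
    if hits is not None:
        write_text_atomic(
            outdir / "hits.tsv", hits.to_csv(sep="\t", index=False, lineterminator="\n")
        )
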