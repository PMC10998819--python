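"""Dominance and persistence classification of OTUs, plus a co-dominance scan.

An OTU is *dominant* when its average relative abundance is at least a
threshold (default 1%) at *every* study site, where a site average is
the unweighted mean over that site's (month x compartment) group
profiles.  Within a compartment an OTU is *persistent* when it is
detected in every sampled month, *seasonal* when it is missing in one
or more (but not all) months, and *absent* when never detected.

The co-dominance scan implements the deviation-minimization idea of
Kikvidze & Ohsawa: for each candidate number of co-dominants k, compare
the ranked abundance vector against an idealized equal-share profile
and take the k with the smallest squared deviation.  Two ideal models
are available: each co-dominant holding 1/k of the *total* community
("community", default), or an equal share of the top-k mass ("topk").
"""

from __future__ import annotations

import dataclasses

import numpy as np
import pandas as pd

from .io import DesignError, OtuCountTable
from .preprocess import GroupProfiles

DOMINANCE_THRESHOLD = 0.01


def rank_otus(profiles: GroupProfiles) -> pd.DataFrame:
    """Rank OTUs by mean relative abundance across all group profiles.

    Returns a DataFrame indexed by OTU with ``overall_mean``, one
    ``mean_<site>`` column per site, and ``rank`` (1 = most abundant;
    ties broken by OTU identifier).
    """
    if len(profiles.data) == 0:
        raise DesignError("no group profiles")
    overall = profiles.data.mean(axis=0)
    site_means = profiles.data.groupby(level="site", observed=True).mean()
    out = pd.DataFrame({"overall_mean": overall})
    for site in site_means.index:
        out[f"mean_{site}"] = site_means.loc[site]
    # descending mean, ties broken by OTU identifier (lexsort: last key primary)
    out = out.iloc[np.lexsort((out.index.to_numpy(), -out["overall_mean"].to_numpy()))]
    out.index.name = "otu_id"
    out["rank"] = np.arange(1, len(out) + 1)
    return out


def classify_dominance(
    records: pd.DataFrame, threshold: float = DOMINANCE_THRESHOLD
) -> pd.DataFrame:
    """Flag OTUs dominant when every site mean clears the threshold."""
    site_cols = [c for c in records.columns if c.startswith("mean_")]
    if not site_cols:
        raise DesignError("records carry no site mean columns")
    out = records.copy()
    out["dominant"] = (out[site_cols] >= threshold).all(axis=1)
    return out


def classify_persistence(
    table: OtuCountTable, metadata: pd.DataFrame, pooled: bool = False
) -> pd.DataFrame:
    """Persistent/seasonal/absent category per OTU x site x compartment.

    Detection in a month means count > 0 in at least one sample of that
    site x month x compartment.  With ``pooled=True`` detection is
    pooled across sites (one category per OTU x compartment), the view
    used when a single P/S label per OTU per compartment is reported.
    """
    meta = metadata.loc[table.sample_ids]
    detected = table.counts > 0
    rows = []
    if pooled:
        months_sampled = meta["month"].astype(str).unique().tolist()
        if not months_sampled:
            raise DesignError("no sampled months")
        for comp, comp_meta in meta.groupby("compartment", observed=True):
            det_month = detected.loc[comp_meta.index].groupby(
                comp_meta["month"].astype(str), observed=True
            ).any()
            n_det = det_month.sum(axis=0)
            n_months = det_month.shape[0]
            for otu in table.otu_ids:
                rows.append(
                    {"otu_id": otu, "compartment": comp,
                     "category": _category(int(n_det[otu]), n_months)}
                )
        return pd.DataFrame(rows)
    for (site, comp), sub in meta.groupby(["site", "compartment"], observed=True):
        months_sampled = sub["month"].astype(str).unique().tolist()
        if not months_sampled:
            raise DesignError(f"site {site} has no sampled months")
        det_month = detected.loc[sub.index].groupby(sub["month"].astype(str), observed=True).any()
        n_det = det_month.sum(axis=0)
        n_months = det_month.shape[0]
        for otu in table.otu_ids:
            rows.append(
                {"otu_id": otu, "site": site, "compartment": comp,
                 "category": _category(int(n_det[otu]), n_months)}
            )
    return pd.DataFrame(rows)


def _category(n_detected: int, n_months: int) -> str:
    if n_detected == 0:
        return "absent"
    if n_detected == n_months:
        return "persistent"
    return "seasonal"


@dataclasses.dataclass(frozen=True)
class CoDominanceResult:
    k: int
    deviation_curve: np.ndarray  # index i -> deviation of k = i + 1
    method: str

    def curve_as_dict(self) -> dict[int, float]:
        return {i + 1: float(v) for i, v in enumerate(self.deviation_curve)}


def kikvidze_ohsawa_k(abundances: np.ndarray, model: str = "community") -> CoDominanceResult:
    """Deviation-minimizing number of co-dominant taxa.

    ``abundances`` are proportions of the whole community (sum <= 1;
    sorted internally).  deviation(k) = sum_{i<=k} (x_i - ideal_k)^2 +
    sum_{i>k} x_i^2, with ideal_k = 1/k ("community" model) or the
    top-k mean ("topk" model); the smallest k wins ties.
    """
    x = np.asarray(abundances, dtype=float)
    if x.size == 0:
        raise DesignError("empty abundance vector")
    if (x < 0).any():
        raise DesignError("abundances must be non-negative")
    if x.sum() > 1 + 1e-9:
        raise DesignError(f"abundances sum to {x.sum():.6f} > 1")
    x = np.sort(x)[::-1]
    if model not in ("community", "topk"):
        raise DesignError(f"unknown ideal model {model!r}")
    n = x.size
    ks = np.arange(1, n + 1)
    csum = np.cumsum(x)
    csq = np.cumsum(x**2)
    total_sq = csq[-1]
    if model == "community":
        ideal = 1.0 / ks
    else:
        ideal = csum / ks
    # sum_{i<=k}(x_i - m)^2 = csq_k - 2 m csum_k + k m^2 ; tail = total_sq - csq_k
    dev = (csq - 2 * ideal * csum + ks * ideal**2) + (total_sq - csq)
    k = int(np.argmin(dev)) + 1  # argmin returns first (smallest k) on ties
    return CoDominanceResult(k=k, deviation_curve=dev, method=f"equal-share-{model}")


def dominance_table(
    ranked: pd.DataFrame,
    persistence: pd.DataFrame,
    threshold: float = DOMINANCE_THRESHOLD,
) -> pd.DataFrame:
    """Join ranking, dominance flags, and per-compartment categories."""
    flagged = classify_dominance(ranked, threshold=threshold)
    wide = persistence.copy()
    key_cols = [c for c in ("site", "compartment") if c in wide.columns]
    wide["key"] = wide[key_cols].agg("_".join, axis=1)
    pivot = wide.pivot(index="otu_id", columns="key", values="category")
    pivot.columns = [f"category_{c}" for c in pivot.columns]
    return flagged.join(pivot)
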