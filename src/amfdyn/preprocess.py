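"""OTU-table preprocessing: rarity filtering, taxonomy labeling, compositions.

The rarity rule discards OTUs with fewer than ``min_total`` reads summed
over all samples or detected (count > 0) in fewer than ``min_samples``
samples.  Both criteria are evaluated on the input table as a single
conjunction, not sequentially.  The taxonomy rule assigns a name only
when the best BLAST hit clears both the query-cover and
percent-identity thresholds; OTUs whose qualifying hits are all
"uncultured Glomeromycotina" are labelled "uncultured", and OTUs with
no qualifying hit are "unclassified".
"""

from __future__ import annotations

import dataclasses

import numpy as np
import pandas as pd

from .io import DesignError, OtuCountTable, TableFormatError

TAXONOMY_THRESHOLD = 95.0
UNCULTURED_TITLE = "uncultured Glomeromycotina"


def filter_rare_otus(
    table: OtuCountTable, min_total: int = 10, min_samples: int = 2
) -> tuple[OtuCountTable, pd.DataFrame]:
    """Drop rare OTUs; returns the filtered table and a removal report.

    An OTU is retained iff total reads >= ``min_total`` AND it is
    detected in >= ``min_samples`` samples.  The report lists each
    removed OTU with its totals and the reason(s).
    """
    totals = table.counts.sum(axis=0)
    prevalence = (table.counts > 0).sum(axis=0)
    keep = (totals >= min_total) & (prevalence >= min_samples)
    if not keep.any():
        raise TableFormatError("rarity filter would remove every OTU")
    removed = []
    for otu in table.counts.columns[~keep]:
        reasons = []
        if totals[otu] < min_total:
            reasons.append(f"total_reads<{min_total}")
        if prevalence[otu] < min_samples:
            reasons.append(f"detected_in<{min_samples}_samples")
        removed.append(
            {
                "otu_id": otu,
                "total_reads": int(totals[otu]),
                "n_samples_detected": int(prevalence[otu]),
                "reason": ";".join(reasons),
            }
        )
    report = pd.DataFrame(removed, columns=["otu_id", "total_reads", "n_samples_detected", "reason"])
    kept = table.counts.loc[:, keep]
    emptied = kept.index[kept.sum(axis=1) == 0].tolist()
    if emptied:
        raise TableFormatError(
            f"rarity filter left samples with zero reads: {emptied}"
        )
    return OtuCountTable(kept), report


@dataclasses.dataclass(frozen=True)
class TaxonomyLabel:
    otu_id: str
    status: str  # assigned | uncultured | unclassified
    taxon: str | None
    best_identity: float | None
    best_cover: float | None


def _best_hit(hits: pd.DataFrame) -> pd.Series:
    # max by (identity, cover), ties broken by subject id for determinism
    order = hits.sort_values(
        ["pident", "qcovs", "sseqid"], ascending=[False, False, True], kind="mergesort"
    )
    return order.iloc[0]


def assign_taxonomy(
    hits: pd.DataFrame,
    threshold: float = TAXONOMY_THRESHOLD,
    otu_ids: list[str] | None = None,
) -> list[TaxonomyLabel]:
    """Apply the best-hit decision rule to a BLAST-tabular hit table.

    ``otu_ids`` may list OTUs with no hits at all; they come back
    "unclassified".  The genus is taken as the first whitespace token of
    the subject title.
    """
    for col in ("pident", "qcovs"):
        vals = pd.to_numeric(hits[col], errors="coerce")
        if vals.isna().any():
            raise TableFormatError(f"malformed percent value in column {col}")
        hits = hits.assign(**{col: vals})
    labels: dict[str, TaxonomyLabel] = {}
    for otu, group in hits.groupby("qseqid", sort=False):
        qualifying = group[(group["pident"] >= threshold) & (group["qcovs"] >= threshold)]
        if qualifying.empty:
            best = _best_hit(group)
            labels[otu] = TaxonomyLabel(otu, "unclassified", None,
                                        float(best["pident"]), float(best["qcovs"]))
            continue
        best = _best_hit(qualifying)
        if (qualifying["stitle"] == UNCULTURED_TITLE).all():
            labels[otu] = TaxonomyLabel(otu, "uncultured", None,
                                        float(best["pident"]), float(best["qcovs"]))
        else:
            named = qualifying[qualifying["stitle"] != UNCULTURED_TITLE]
            best = _best_hit(named)
            genus = str(best["stitle"]).split()[0]
            labels[otu] = TaxonomyLabel(otu, "assigned", genus,
                                        float(best["pident"]), float(best["qcovs"]))
    ordered = otu_ids if otu_ids is not None else list(labels)
    out = []
    for otu in ordered:
        out.append(labels.get(otu, TaxonomyLabel(otu, "unclassified", None, None, None)))
    return out


def taxonomy_table(labels: list[TaxonomyLabel]) -> pd.DataFrame:
    return pd.DataFrame(
        [
            {
                "otu_id": lab.otu_id,
                "status": lab.status,
                "taxon": lab.taxon or "",
                "pident": lab.best_identity,
                "qcovs": lab.best_cover,
            }
            for lab in labels
        ]
    )


def relative_abundance(table: OtuCountTable) -> pd.DataFrame:
    """Within-sample compositions; every row sums to 1."""
    sums = table.counts.sum(axis=1)
    if (sums == 0).any():
        raise TableFormatError("zero-sum sample row")
    return table.counts.div(sums, axis=0)


@dataclasses.dataclass(frozen=True)
class GroupProfiles:
    """Mean composition per (site, month, compartment) group.

    ``data`` rows are unweighted means of the member samples'
    compositions, so each row itself sums to 1.
    """

    data: pd.DataFrame  # MultiIndex (site, month, compartment) x OTUs
    n_samples: pd.Series

    def site_groups(self, site: str) -> pd.DataFrame:
        return self.data.xs(site, level="site", drop_level=False)


def group_profiles(composition: pd.DataFrame, metadata: pd.DataFrame) -> GroupProfiles:
    """Average per-sample compositions within site x month x compartment."""
    missing = sorted(set(composition.index) - set(metadata.index))
    if missing:
        raise DesignError(f"samples without metadata: {missing}")
    meta = metadata.loc[composition.index]
    keys = [meta["site"], meta["month"], meta["compartment"]]
    grouped = composition.groupby(keys, observed=True, sort=True)
    data = grouped.mean()
    n = grouped.size()
    if (n == 0).any():
        empty = n.index[n == 0].tolist()
        raise DesignError(f"empty group(s): {empty}")
    data.index.names = ["site", "month", "compartment"]
    n.index.names = ["site", "month", "compartment"]
    return GroupProfiles(data=data, n_samples=n)


def genus_composition(composition: pd.DataFrame, labels: list[TaxonomyLabel]) -> pd.DataFrame:
    """Aggregate per-sample proportions to genus level.

    "uncultured" and "unclassified" OTUs are kept as their own
    categories; total proportion per sample is conserved.
    """
    by_otu = {lab.otu_id: lab for lab in labels}
    unlabeled = sorted(set(composition.columns) - set(by_otu))
    if unlabeled:
        raise DesignError(f"OTUs without taxonomy labels: {unlabeled[:5]}")
    cat = {}
    for otu in composition.columns:
        lab = by_otu[otu]
        cat[otu] = lab.taxon if lab.status == "assigned" else lab.status
    return composition.T.groupby(pd.Series(cat), sort=True).sum().T
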