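"""rRNA:rDNA relative-activity framework.

For every station-depth with both templates sequenced, each OTU detected in
BOTH templates gets one ratio: its relative abundance in the RNA survey
divided by its relative abundance in the DNA survey.  OTUs absent from
either template of that pair yield no record — zeros exclude, they are
never inflated with pseudo-counts — so every stored ratio is finite and
positive.  Ratios well above 1 flag hyperactive taxa, well below 1
hypoactive taxa; ratios around 1 indicate average activity.

Group-by-layer contrasts pool all OTU-sample ratios of a group within each
layer and compare layers with two-sided rank-sum (Wilcoxon) tests,
Benjamini-Hochberg corrected across the pairwise layer comparisons of the
group.
"""

from __future__ import annotations

import itertools
import logging
from dataclasses import dataclass, field
from typing import NamedTuple

import numpy as np
import pandas as pd
from scipy.stats import mannwhitneyu
from statsmodels.stats.multitest import multipletests

from .core_tables import (
    LAYERS,
    RelAbundanceTable,
    SampleInfo,
    TaxonAssignment,
    taxonomy_map,
)

logger = logging.getLogger(__name__)

#: Default "about 1" band: within two-fold of parity.  The band is a
#: mandatory analysis parameter and is echoed in all output headers.
DEFAULT_ACTIVITY_BAND = (0.5, 2.0)


@dataclass(frozen=True)
class SamplePair:
    """One station-depth with exactly one rDNA and one rRNA sample."""

    station: str
    depth_m: float
    layer: str
    rdna_sample_id: str
    rrna_sample_id: str


class ActivityRecord(NamedTuple):
    """One finite, positive rRNA:rDNA ratio for one OTU in one sample pair."""

    otu_id: str
    pair: SamplePair
    group: str
    ratio: float


@dataclass
class LayerContrast:
    group: str
    layer_medians: dict[str, float]
    pairwise_p: dict[tuple[str, str], float]
    pairwise_p_adjusted: dict[tuple[str, str], float]
    significantly_high: set[str] = field(default_factory=set)
    significantly_low: set[str] = field(default_factory=set)


def pair_samples(meta: list[SampleInfo]) -> list[SamplePair]:
    """Match rDNA and rRNA samples by (station, depth).

    Station-depths missing a template are logged and skipped; two samples
    of the same template at one station-depth is an error.
    """
    cells: dict[tuple[str, float], dict[str, SampleInfo]] = {}
    for m in meta:
        key = (m.station, m.depth_m)
        slot = cells.setdefault(key, {})
        if m.template in slot:
            raise ValueError(
                f"duplicate {m.template} sample at station {m.station}, "
                f"{m.depth_m} m ({slot[m.template].sample_id}, {m.sample_id})"
            )
        slot[m.template] = m
    pairs: list[SamplePair] = []
    for (station, depth), slot in sorted(cells.items()):
        if "rDNA" in slot and "rRNA" in slot:
            pairs.append(
                SamplePair(
                    station=station,
                    depth_m=depth,
                    layer=slot["rDNA"].layer,
                    rdna_sample_id=slot["rDNA"].sample_id,
                    rrna_sample_id=slot["rRNA"].sample_id,
                )
            )
        else:
            have = ", ".join(slot)
            logger.info(
                "pair_samples: station %s at %s m has only %s; skipped",
                station, depth, have,
            )
    return pairs


def activity_ratios(
    rdna_rel: RelAbundanceTable,
    rrna_rel: RelAbundanceTable,
    pairs: list[SamplePair],
    tax: list[TaxonAssignment] | None = None,
    require_both_datasets: bool = False,
) -> list[ActivityRecord]:
    """One ratio p_RNA / p_DNA per (pair, OTU) detected in both templates.

    ``require_both_datasets`` additionally pre-filters to OTUs detected
    somewhere in BOTH whole tables (the whole-dataset reading of the
    exclusion rule); the per-pair zero exclusion always applies.
    """
    groups = taxonomy_map(tax) if tax else {}
    rrna_otus = set(rrna_rel.otu_ids)
    otus = [o for o in rdna_rel.otu_ids if o in rrna_otus]
    dna = rdna_rel.data.loc[otus]
    rna = rrna_rel.data.loc[otus]
    if require_both_datasets:
        keep = (dna.sum(axis=1) > 0) & (rna.sum(axis=1) > 0)
        dna, rna = dna.loc[keep], rna.loc[keep]
        otus = list(dna.index)
    otu_arr = np.asarray(otus)
    records: list[ActivityRecord] = []
    for pair in pairs:
        if pair.rdna_sample_id not in dna.columns:
            raise ValueError(f"pair references missing sample {pair.rdna_sample_id!r}")
        if pair.rrna_sample_id not in rna.columns:
            raise ValueError(f"pair references missing sample {pair.rrna_sample_id!r}")
        p_dna = dna[pair.rdna_sample_id].to_numpy()
        p_rna = rna[pair.rrna_sample_id].to_numpy()
        both = (p_dna > 0) & (p_rna > 0)
        ratios = p_rna[both] / p_dna[both]
        for oid, r in zip(otu_arr[both], ratios):
            records.append(
                ActivityRecord(
                    otu_id=str(oid),
                    pair=pair,
                    group=groups.get(str(oid), "unassigned"),
                    ratio=float(r),
                )
            )
    return records


def classify_activity(
    ratio_or_record,
    band: tuple[float, float] = DEFAULT_ACTIVITY_BAND,
) -> str:
    """'hyperactive' above the band, 'hypoactive' below, else 'average'."""
    low, high = band
    if not (0 < low < 1 < high):
        raise ValueError(f"invalid activity band {band!r}: need 0 < low < 1 < high")
    ratio = ratio_or_record.ratio if hasattr(ratio_or_record, "ratio") else ratio_or_record
    if ratio > high:
        return "hyperactive"
    if ratio < low:
        return "hypoactive"
    return "average"


def records_frame(records: list[ActivityRecord]) -> pd.DataFrame:
    """Flatten activity records (one row per OTU-pair ratio)."""
    return pd.DataFrame(
        {
            "otu_id": [r.otu_id for r in records],
            "station": [r.pair.station for r in records],
            "depth_m": [r.pair.depth_m for r in records],
            "layer": [r.pair.layer for r in records],
            "group": [r.group for r in records],
            "ratio": [r.ratio for r in records],
        }
    )


def layer_contrasts(
    records: list[ActivityRecord],
    alpha: float = 0.05,
    min_per_cell: int = 2,
    correction: str = "fdr_bh",
) -> list[LayerContrast]:
    """Per-group layer contrasts of pooled OTU-sample ratios.

    A layer is ``significantly_high`` for a group when every pairwise
    rank-sum test against the other layers is significant at ``alpha``
    after the multiplicity correction AND the layer is stochastically
    higher in each of them (common-language effect size P(X > Y) > 1/2);
    symmetric rule for ``significantly_low``.  Direction comes from the
    test's own effect size rather than the sample medians because pooled
    count-ratio medians can tie exactly (e.g., at 1.0) even between clearly
    different distributions; medians are still reported.
    """
    df = records_frame(records)
    contrasts: list[LayerContrast] = []
    for group, sub in df.groupby("group", sort=True):
        cells = {
            layer: sub.loc[sub["layer"] == layer, "ratio"].to_numpy()
            for layer in LAYERS
        }
        cells = {k: v for k, v in cells.items() if len(v) >= min_per_cell}
        if len(cells) < 2:
            logger.info("layer_contrasts: group %r has <2 layers of data; skipped", group)
            continue
        medians = {layer: float(np.median(v)) for layer, v in cells.items()}
        combos = list(itertools.combinations(sorted(cells, key=LAYERS.index), 2))
        raw = {}
        effect = {}  # (a, b) -> P(ratio_a > ratio_b), ties counted half
        for a, b in combos:
            if np.array_equal(cells[a], cells[b]):
                raw[(a, b)] = 1.0
                effect[(a, b)] = 0.5
            else:
                res = mannwhitneyu(cells[a], cells[b], alternative="two-sided")
                raw[(a, b)] = float(res.pvalue)
                effect[(a, b)] = float(res.statistic) / (len(cells[a]) * len(cells[b]))
        adj_values = multipletests(list(raw.values()), method=correction)[1]
        adj = dict(zip(raw.keys(), adj_values))

        def wins_all(layer: str, higher: bool) -> bool:
            for a, b in combos:
                if layer not in (a, b):
                    continue
                if adj[(a, b)] > alpha:
                    return False
                p_layer_gt = effect[(a, b)] if layer == a else 1.0 - effect[(a, b)]
                if higher and not p_layer_gt > 0.5:
                    return False
                if not higher and not p_layer_gt < 0.5:
                    return False
            return True

        high = {layer for layer in cells if wins_all(layer, True)}
        low = {layer for layer in cells if wins_all(layer, False)}
        contrasts.append(
            LayerContrast(
                group=str(group),
                layer_medians=medians,
                pairwise_p=raw,
                pairwise_p_adjusted=adj,
                significantly_high=high,
                significantly_low=low,
            )
        )
    return contrasts


@dataclass(frozen=True)
class LayerAssignment:
    layer: str | None            # None when the maximum is tied (ambiguous)
    medians: dict[str, float]
    ambiguous: bool


def layer_of_max_activity(
    records: list[ActivityRecord],
    min_layers: int = 4,
) -> dict[str, LayerAssignment]:
    """Assign each OTU present in all four layers to the layer where its
    median ratio peaks; exact ties make the OTU ambiguous (excluded from
    downstream layer sets)."""
    df = records_frame(records)
    out: dict[str, LayerAssignment] = {}
    for otu, sub in df.groupby("otu_id", sort=True):
        present = sub["layer"].unique()
        if len(present) < min_layers:
            continue
        medians = {
            layer: float(np.median(sub.loc[sub["layer"] == layer, "ratio"]))
            for layer in LAYERS
            if layer in set(present)
        }
        peak = max(medians.values())
        argmax = [layer for layer, v in medians.items() if v == peak]
        if len(argmax) > 1:
            out[str(otu)] = LayerAssignment(None, medians, True)
        else:
            out[str(otu)] = LayerAssignment(argmax[0], medians, False)
    return out


def layer_sets(assignments: dict[str, LayerAssignment]) -> dict[str, set[str]]:
    """Unambiguous OTU sets per layer of maximum activity."""
    sets: dict[str, set[str]] = {layer: set() for layer in LAYERS}
    for otu, a in assignments.items():
        if not a.ambiguous and a.layer is not None:
            sets[a.layer].add(otu)
    return sets
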