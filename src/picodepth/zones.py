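"""Mesopelagic zone contrasts: oxygen minimum zone (OMZ) and deep
scattering layer (DSL) versus the remaining mesopelagic samples.

Per taxonomic group, two quantities against the complement: the ratio of
mean relative abundance and the ratio of median rRNA:rDNA activity.  Groups
below a mesopelagic read-share threshold are excluded; groups with data on
only one side are reported with a reason code instead of an infinite ratio.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
from scipy.stats import mannwhitneyu

from .activity import ActivityRecord, records_frame
from .core_tables import (
    RelAbundanceTable,
    SampleInfo,
    TaxonAssignment,
    aggregate_by_group,
)

logger = logging.getLogger(__name__)

DEFAULT_SHARE_THRESHOLD = 0.0005  # 0.05% of mesopelagic reads


@dataclass
class ZoneSplit:
    zone: str                       # "OMZ" or "DSL"
    zone_samples: list[str]
    complement_samples: list[str]
    zone_cells: set[tuple[str, float]]        # (station, depth) in zone
    complement_cells: set[tuple[str, float]]


@dataclass
class ZoneContrast:
    group: str
    mesopelagic_share: float
    abundance_ratio: float | None      # mean in zone / mean outside
    activity_ratio: float | None       # median ratio in zone / outside
    included: bool
    reason: str = ""                   # set when a ratio is undefined


@dataclass
class RichnessContrast:
    zone_median: float
    complement_median: float
    statistic: float
    p_value: float
    n_zone: int
    n_complement: int


def define_zone(
    meta: list[SampleInfo],
    zone: str,
    template: str | None = None,
) -> ZoneSplit:
    """Split the mesopelagic samples of ``meta`` into zone and complement.

    OMZ membership comes from the derived oxygen flag (O2 below threshold,
    strict), DSL from the metadata flag.  Optionally restrict to one
    template.  Both sides must be non-empty.
    """
    if zone not in ("OMZ", "DSL"):
        raise ValueError("zone must be 'OMZ' or 'DSL'")
    meso = [m for m in meta if m.layer == "mesopelagic"]
    if template is not None:
        meso = [m for m in meso if m.template == template]
    if not meso:
        raise ValueError("no mesopelagic samples")
    flag = (lambda m: m.omz) if zone == "OMZ" else (lambda m: m.dsl)
    zone_samples = [m.sample_id for m in meso if flag(m)]
    complement = [m.sample_id for m in meso if not flag(m)]
    if not zone_samples:
        raise ValueError(f"empty zone: no {zone} mesopelagic samples")
    if not complement:
        raise ValueError(f"empty complement: every mesopelagic sample is {zone}")
    return ZoneSplit(
        zone=zone,
        zone_samples=zone_samples,
        complement_samples=complement,
        zone_cells={(m.station, m.depth_m) for m in meso if flag(m)},
        complement_cells={(m.station, m.depth_m) for m in meso if not flag(m)},
    )


def zone_contrast(
    rel_table: RelAbundanceTable,
    activity_records: list[ActivityRecord],
    tax: list[TaxonAssignment],
    zone_split: ZoneSplit,
    share_threshold: float = DEFAULT_SHARE_THRESHOLD,
    abundance_stat: str = "mean",
    activity_stat: str = "median",
) -> list[ZoneContrast]:
    """Per-group abundance and activity ratios, zone vs complement.

    ``rel_table`` supplies the abundance side (rRNA by default upstream);
    its columns must cover both sample sets.  Activity ratios use the
    records whose pair (station, depth) falls in each side.  A group is
    reported iff its share of total mesopelagic reads strictly exceeds
    ``share_threshold``.
    """
    agg_fun = {"mean": np.mean, "median": np.median}[abundance_stat]
    act_fun = {"mean": np.mean, "median": np.median}[activity_stat]
    zone_ids = [s for s in zone_split.zone_samples if s in rel_table.sample_ids]
    comp_ids = [s for s in zone_split.complement_samples if s in rel_table.sample_ids]
    if not zone_ids or not comp_ids:
        raise ValueError("relative-abundance table does not cover both sides")
    groups = aggregate_by_group(rel_table, tax)
    meso_ids = zone_ids + comp_ids
    share = groups[meso_ids].sum(axis=1) / len(meso_ids)

    act = records_frame(activity_records)
    act["cell"] = list(zip(act["station"], act["depth_m"]))
    in_zone = act["cell"].isin(zone_split.zone_cells)
    in_comp = act["cell"].isin(zone_split.complement_cells)

    out: list[ZoneContrast] = []
    for group in groups.index:
        g_share = float(share[group])
        if not g_share > share_threshold:
            continue
        zone_ab = groups.loc[group, zone_ids].to_numpy(dtype=float)
        comp_ab = groups.loc[group, comp_ids].to_numpy(dtype=float)
        mean_zone, mean_comp = float(agg_fun(zone_ab)), float(agg_fun(comp_ab))
        reason = ""
        if mean_zone > 0 and mean_comp > 0:
            ab_ratio = mean_zone / mean_comp
        else:
            ab_ratio = None
            reason = "zone_only" if mean_zone > 0 else "complement_only"
            if mean_zone == 0 and mean_comp == 0:
                reason = "absent"
        g_act = act[act["group"] == group]
        zr = g_act.loc[in_zone, "ratio"].to_numpy()
        cr = g_act.loc[in_comp, "ratio"].to_numpy()
        if len(zr) and len(cr):
            act_ratio = float(act_fun(zr)) / float(act_fun(cr))
        else:
            act_ratio = None
            if not reason:
                reason = "no_activity_records"
        out.append(
            ZoneContrast(
                group=str(group),
                mesopelagic_share=g_share,
                abundance_ratio=ab_ratio,
                activity_ratio=act_ratio,
                included=True,
                reason=reason,
            )
        )
    return out


def zone_richness_contrast(table, zone_split: ZoneSplit) -> RichnessContrast:
    """Two-sided rank-sum test of per-sample richness, zone vs complement.

    ``table`` should hold rarefied counts so richness is comparable.
    """
    data = table.data
    zone_ids = [s for s in zone_split.zone_samples if s in data.columns]
    comp_ids = [s for s in zone_split.complement_samples if s in data.columns]
    if len(zone_ids) < 2 or len(comp_ids) < 2:
        raise ValueError("need >= 2 samples on each side")
    rich_zone = (data[zone_ids] > 0).sum(axis=0).to_numpy(dtype=float)
    rich_comp = (data[comp_ids] > 0).sum(axis=0).to_numpy(dtype=float)
    if np.array_equal(rich_zone, rich_comp):
        stat, p = float(len(rich_zone) * len(rich_comp) / 2.0), 1.0
    else:
        res = mannwhitneyu(rich_zone, rich_comp, alternative="two-sided")
        stat, p = float(res.statistic), float(res.pvalue)
    return RichnessContrast(
        zone_median=float(np.median(rich_zone)),
        complement_median=float(np.median(rich_comp)),
        statistic=stat,
        p_value=p,
        n_zone=len(zone_ids),
        n_complement=len(comp_ids),
    )
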