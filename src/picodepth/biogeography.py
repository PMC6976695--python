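"""Horizontal community structure within depth strata.

Distance distributions per layer (how similar are communities of the same
layer across stations), OTU prevalence curves (in how many stations is an
OTU detected), and layer-restricted / shared OTU bookkeeping.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from skbio import DistanceMatrix

from .core_tables import LAYERS, OtuTable, SampleInfo

logger = logging.getLogger(__name__)


@dataclass
class PrevalenceCurve:
    layer: str
    counts: dict[int, int]          # n_stations -> number of OTUs seen in exactly n
    fraction_prevalent: float       # OTUs present in >= q of stations
    q: float
    n_stations: int

    @property
    def total_otus(self) -> int:
        return sum(self.counts.values())


def _meta_index(meta: list[SampleInfo]) -> dict[str, SampleInfo]:
    return {m.sample_id: m for m in meta}


def layer_dissimilarity_distributions(
    d: DistanceMatrix,
    meta: list[SampleInfo],
    stratum: str = "layer",
    one_per_station: bool = True,
) -> dict[str, np.ndarray]:
    """All pairwise dissimilarities among the samples of each stratum.

    ``stratum`` is ``"layer"`` or ``"sublayer"``.  With ``one_per_station``
    (the study convention of comparing one sample of each water layer among
    stations) only the shallowest sample per station enters each stratum.
    Strata with fewer than 2 samples are skipped with a log line.
    """
    if stratum not in ("layer", "sublayer"):
        raise ValueError("stratum must be 'layer' or 'sublayer'")
    info = _meta_index(meta)
    ids = [s for s in d.ids if s in info]
    by_stratum: dict[str, list[str]] = {}
    for sid in ids:
        m = info[sid]
        key = m.layer if stratum == "layer" else (m.sublayer or m.layer)
        by_stratum.setdefault(key, []).append(sid)
    out: dict[str, np.ndarray] = {}
    for key, members in by_stratum.items():
        if one_per_station:
            chosen: dict[str, str] = {}
            for sid in members:
                st = info[sid].station
                if st not in chosen or info[sid].depth_m < info[chosen[st]].depth_m:
                    chosen[st] = sid
            members = list(chosen.values())
        if len(members) < 2:
            logger.info(
                "layer_dissimilarity_distributions: stratum %r has <2 samples; skipped",
                key,
            )
            continue
        sub = d.filter(members)
        iu = np.triu_indices(len(members), 1)
        out[key] = sub.data[iu]
    return out


def _detection_by_station(
    table: OtuTable, meta: list[SampleInfo], layer: str
) -> pd.DataFrame:
    """Boolean OTU x station detection matrix within one layer."""
    info = _meta_index(meta)
    cols = [s for s in table.sample_ids if s in info and info[s].layer == layer]
    stations = sorted({info[s].station for s in cols})
    det = pd.DataFrame(False, index=table.otu_ids, columns=stations)
    for s in cols:
        det[info[s].station] |= table.data[s] > 0
    return det


def prevalence_curves(
    table: OtuTable,
    meta: list[SampleInfo],
    layer: str,
    q: float = 0.8,
) -> PrevalenceCurve:
    """Number of OTUs of a layer detected in exactly n stations, n = 1..N,
    plus the fraction detected in at least ``q`` of the stations."""
    det = _detection_by_station(table, meta, layer)
    n_stations = det.shape[1]
    hits = det.sum(axis=1)
    hits = hits[hits > 0]
    counts = {
        n: int((hits == n).sum()) for n in range(1, n_stations + 1)
    }
    detected = int(len(hits))
    prevalent = int((hits >= q * n_stations).sum())
    frac = prevalent / detected if detected else 0.0
    return PrevalenceCurve(layer, counts, frac, q, n_stations)


def layer_restricted_otus(
    table: OtuTable,
    meta: list[SampleInfo],
    min_reads: int = 5,
    per_sample: bool = False,
) -> dict[str, tuple[set[str], float]]:
    """OTUs whose reads fall entirely within one layer.

    Only OTUs with total reads strictly greater than ``min_reads`` enter
    the analysis (``per_sample=True`` instead requires > min_reads in at
    least one sample).  Fractions are over the filtered OTU set.
    """
    info = _meta_index(meta)
    data = table.data
    totals = data.sum(axis=1)
    if per_sample:
        eligible = (data > min_reads).any(axis=1)
    else:
        eligible = totals > min_reads
    filtered = data.loc[eligible]
    n_filtered = filtered.shape[0]
    layer_of = {s: info[s].layer for s in data.columns if s in info}
    reads_by_layer = pd.DataFrame(
        {
            layer: filtered[[s for s, l in layer_of.items() if l == layer]].sum(axis=1)
            for layer in LAYERS
        }
    )
    total = reads_by_layer.sum(axis=1)
    out: dict[str, tuple[set[str], float]] = {}
    for layer in LAYERS:
        restricted = set(
            reads_by_layer.index[
                (reads_by_layer[layer] == total) & (total > 0)
            ]
        )
        out[layer] = (restricted, len(restricted) / n_filtered if n_filtered else 0.0)
    return out


def shared_otu_matrix(table: OtuTable, meta: list[SampleInfo]) -> pd.DataFrame:
    """Symmetric 4x4 matrix of OTUs detected in both layers of each pair;
    the diagonal counts OTUs detected in that layer."""
    info = _meta_index(meta)
    detected = {}
    for layer in LAYERS:
        cols = [s for s in table.sample_ids if s in info and info[s].layer == layer]
        detected[layer] = (table.data[cols].sum(axis=1) > 0) if cols else (
            pd.Series(False, index=table.otu_ids)
        )
    mat = pd.DataFrame(0, index=list(LAYERS), columns=list(LAYERS))
    for a in LAYERS:
        for b in LAYERS:
            mat.loc[a, b] = int((detected[a] & detected[b]).sum())
    return mat
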