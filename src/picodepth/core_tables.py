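"""OTU tables, sample metadata and the bookkeeping operations around them.

The data model mirrors a paired-template 18S amplicon survey: one count
table per nucleic-acid template (rDNA for community standing stock, rRNA
for the ribosome pool), a per-sample design/environment record, and an
OTU-to-taxonomic-group map.  Everything downstream (diversity, activity
ratios, biogeography, zone contrasts) consumes these containers.

All table I/O is plain UTF-8 TSV with ``.`` decimal points and no quoting.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

LAYERS = ("surface", "DCM", "mesopelagic", "bathypelagic")
SUBLAYERS = ("meso_upper", "meso_lower", "bathy_upper", "bathy_lower")
TEMPLATES = ("rDNA", "rRNA")
OCEANS = ("Atlantic", "Indian", "Pacific")

#: Group label under which OTUs without a taxonomic assignment are pooled.
UNASSIGNED_GROUP = "IncertaeSedis Eukaryota"

TROPHIC_MODES = ("phototrophic", "heterotrophic", "mixotrophic", "unknown")

#: Default oxygen threshold (mg O2 / L) below which a mesopelagic sample
#: counts as an oxygen-minimum-zone (OMZ) sample; strict ``<`` comparison.
DEFAULT_OMZ_THRESHOLD = 2.0


@dataclass(frozen=True)
class LayerBounds:
    """Depth boundaries (m) used to check layer labels and derive sublayers.

    Surface samples sit above ``surface_max``; the DCM is a metadata flag
    (its depth varies by station and is never inferred from depth alone);
    mesopelagic spans (meso_min, meso_max]; bathypelagic (meso_max,
    bathy_max].  ``meso_split`` / ``bathy_split`` cut each dark-ocean layer
    into an upper and a lower sublayer.
    """

    surface_max: float = 10.0
    meso_min: float = 200.0
    meso_max: float = 1000.0
    bathy_max: float = 4000.0
    meso_split: float = 500.0
    bathy_split: float = 2000.0

    def check_layer(self, layer: str, depth_m: float) -> bool:
        if layer == "surface":
            return depth_m <= self.surface_max
        if layer == "DCM":
            # photic, below surface bin, above the mesopelagic
            return depth_m <= self.meso_min
        if layer == "mesopelagic":
            return self.meso_min < depth_m <= self.meso_max
        if layer == "bathypelagic":
            return self.meso_max < depth_m <= self.bathy_max
        raise ValueError(f"unknown layer {layer!r}")

    def sublayer(self, layer: str, depth_m: float) -> str | None:
        if layer == "mesopelagic":
            return "meso_upper" if depth_m <= self.meso_split else "meso_lower"
        if layer == "bathypelagic":
            return "bathy_upper" if depth_m <= self.bathy_split else "bathy_lower"
        return None


def _check_ids(values, what: str) -> list[str]:
    ids = [str(v) for v in values]
    seen: set[str] = set()
    for v in ids:
        if v in seen:
            raise ValueError(f"duplicate {what} id: {v!r}")
        seen.add(v)
    return ids


class OtuTable:
    """Non-negative integer read-count matrix, OTUs (rows) x samples (cols)."""

    def __init__(self, data: pd.DataFrame):
        _check_ids(data.index, "OTU")
        _check_ids(data.columns, "sample")
        values = data.to_numpy()
        if not np.issubdtype(values.dtype, np.integer):
            as_float = np.asarray(values, dtype=float)
            if not np.all(as_float == np.floor(as_float)):
                bad = np.argwhere(as_float != np.floor(as_float))[0]
                raise ValueError(
                    "non-integer count at OTU "
                    f"{data.index[bad[0]]!r}, sample {data.columns[bad[1]]!r}"
                )
            values = as_float.astype(np.int64)
        if (values < 0).any():
            bad = np.argwhere(values < 0)[0]
            raise ValueError(
                f"negative count at OTU {data.index[bad[0]]!r}, "
                f"sample {data.columns[bad[1]]!r}"
            )
        self._data = pd.DataFrame(
            values.astype(np.int64),
            index=[str(i) for i in data.index],
            columns=[str(c) for c in data.columns],
        )
        self._data.index.name = "otu_id"

    @property
    def data(self) -> pd.DataFrame:
        return self._data

    @property
    def otu_ids(self) -> list[str]:
        return list(self._data.index)

    @property
    def sample_ids(self) -> list[str]:
        return list(self._data.columns)

    @property
    def shape(self) -> tuple[int, int]:
        return self._data.shape

    def column_sums(self) -> pd.Series:
        return self._data.sum(axis=0)

    def total_reads(self) -> int:
        return int(self._data.to_numpy().sum())

    def select_samples(self, sample_ids) -> "OtuTable":
        return OtuTable(self._data.loc[:, list(sample_ids)])

    def drop_empty_otus(self) -> "OtuTable":
        keep = self._data.sum(axis=1) > 0
        return OtuTable(self._data.loc[keep])

    def __eq__(self, other) -> bool:
        return isinstance(other, OtuTable) and self._data.equals(other._data)

    def __repr__(self) -> str:
        return f"OtuTable({self.shape[0]} OTUs x {self.shape[1]} samples)"


class RelAbundanceTable:
    """Per-sample relative abundances; every column sums to 1 (tol 1e-9)."""

    def __init__(self, data: pd.DataFrame):
        _check_ids(data.index, "OTU")
        _check_ids(data.columns, "sample")
        values = np.asarray(data.to_numpy(), dtype=float)
        if (values < 0).any():
            raise ValueError("negative proportion")
        colsums = values.sum(axis=0)
        bad = np.where(np.abs(colsums - 1.0) > 1e-9)[0]
        if bad.size:
            raise ValueError(
                f"column {data.columns[bad[0]]!r} sums to {colsums[bad[0]]!r}, not 1"
            )
        self._data = pd.DataFrame(values, index=data.index, columns=data.columns)
        self._data.index.name = "otu_id"

    @property
    def data(self) -> pd.DataFrame:
        return self._data

    @property
    def otu_ids(self) -> list[str]:
        return list(self._data.index)

    @property
    def sample_ids(self) -> list[str]:
        return list(self._data.columns)

    def select_samples(self, sample_ids) -> "RelAbundanceTable":
        return RelAbundanceTable(self._data.loc[:, list(sample_ids)])


@dataclass
class SampleInfo:
    """Design and environmental record for one sequenced sample."""

    sample_id: str
    station: str
    depth_m: float
    layer: str
    ocean: str
    template: str
    temperature_C: float
    salinity: float
    oxygen_mg_L: float
    light: bool
    dsl: bool
    sublayer: str | None = None
    nutrients: dict[str, float] = field(default_factory=dict)
    water_mass: dict[str, float] = field(default_factory=dict)
    omz: bool = False

    def validate(self, bounds: LayerBounds = LayerBounds()) -> None:
        if self.layer not in LAYERS:
            raise ValueError(f"{self.sample_id}: unknown layer {self.layer!r}")
        if self.ocean not in OCEANS:
            raise ValueError(f"{self.sample_id}: unknown ocean {self.ocean!r}")
        if self.template not in TEMPLATES:
            raise ValueError(f"{self.sample_id}: unknown template {self.template!r}")
        if self.depth_m < 0:
            raise ValueError(f"{self.sample_id}: negative depth")
        if self.oxygen_mg_L < 0:
            raise ValueError(f"{self.sample_id}: negative oxygen")
        if not bounds.check_layer(self.layer, self.depth_m):
            raise ValueError(
                f"{self.sample_id}: layer {self.layer!r} inconsistent with "
                f"depth {self.depth_m} m"
            )
        if self.water_mass:
            total = sum(self.water_mass.values())
            if abs(total - 1.0) > 1e-6:
                raise ValueError(
                    f"{self.sample_id}: water-mass fractions sum to {total}, not 1"
                )


@dataclass(frozen=True)
class TaxonAssignment:
    otu_id: str
    group: str
    trophic_mode: str = "unknown"

    def __post_init__(self):
        if not self.group:
            raise ValueError(f"{self.otu_id}: empty group")
        if self.trophic_mode not in TROPHIC_MODES:
            raise ValueError(
                f"{self.otu_id}: unknown trophic mode {self.trophic_mode!r}"
            )


# ---------------------------------------------------------------------------
# I/O
# ---------------------------------------------------------------------------

def read_otu_table(path) -> OtuTable:
    """Read a TSV OTU table (first column ``otu_id``, header = sample ids).

    Rejects duplicated ids and negative or non-integer cells, naming the
    offending coordinates.  Row and column order are preserved.
    """
    # check the raw header first: pandas de-duplicates repeated column names
    with open(path, encoding="utf-8") as fh:
        header = fh.readline().rstrip("\n").split("\t")
    _check_ids(header[1:], "sample")
    df = pd.read_csv(path, sep="\t", header=0, index_col=0, dtype=str)
    _check_ids(df.index, "OTU")
    try:
        counts = df.astype(np.int64)
    except (ValueError, TypeError):
        numeric = df.apply(pd.to_numeric, errors="coerce")
        bad = np.argwhere(numeric.isna().to_numpy() | (numeric.to_numpy() % 1 != 0))
        if bad.size:
            r, c = bad[0]
            raise ValueError(
                f"non-integer cell at OTU {df.index[r]!r}, sample {df.columns[c]!r}"
            ) from None
        counts = numeric.astype(np.int64)
    return OtuTable(counts)


def write_otu_table(table: OtuTable, path) -> None:
    table.data.to_csv(path, sep="\t", index_label="otu_id")


_METADATA_REQUIRED = (
    "sample_id", "station", "depth_m", "layer", "ocean", "template",
    "temperature_C", "salinity", "oxygen_mg_L", "light", "dsl",
)

_BOOL_MAP = {"true": True, "false": False, "1": True, "0": False,
             "yes": True, "no": False}


def _parse_bool(value, column: str, sample: str) -> bool:
    if isinstance(value, (bool, np.bool_)):
        return bool(value)
    key = str(value).strip().lower()
    if key not in _BOOL_MAP:
        raise ValueError(f"{sample}: unparsable boolean {value!r} in column {column}")
    return _BOOL_MAP[key]


def read_metadata(
    path,
    omz_threshold: float = DEFAULT_OMZ_THRESHOLD,
    bounds: LayerBounds = LayerBounds(),
) -> list[SampleInfo]:
    """Read the sample sheet and derive per-sample flags.

    ``omz`` is derived as ``oxygen_mg_L < omz_threshold`` (strict, default
    2 mg O2/L).  Water-mass columns are prefixed ``wm_`` (fractions summing
    to 1 where present), nutrient columns ``nut_`` (µM).  Sublayers are
    derived from depth via ``bounds``.
    """
    if omz_threshold <= 0:
        raise ValueError("omz_threshold must be > 0")
    df = pd.read_csv(path, sep="\t", header=0, dtype=str)
    missing = [c for c in _METADATA_REQUIRED if c not in df.columns]
    if missing:
        raise ValueError(f"metadata missing required column(s): {missing}")
    wm_cols = [c for c in df.columns if c.startswith("wm_")]
    nut_cols = [c for c in df.columns if c.startswith("nut_")]
    records: list[SampleInfo] = []
    for _, row in df.iterrows():
        sid = str(row["sample_id"])
        depth = float(row["depth_m"])
        layer = str(row["layer"])
        wm = {
            c[3:]: float(row[c])
            for c in wm_cols
            if str(row[c]) not in ("", "nan")
        }
        nuts = {
            c[4:]: float(row[c])
            for c in nut_cols
            if str(row[c]) not in ("", "nan")
        }
        info = SampleInfo(
            sample_id=sid,
            station=str(row["station"]),
            depth_m=depth,
            layer=layer,
            ocean=str(row["ocean"]),
            template=str(row["template"]),
            temperature_C=float(row["temperature_C"]),
            salinity=float(row["salinity"]),
            oxygen_mg_L=float(row["oxygen_mg_L"]),
            light=_parse_bool(row["light"], "light", sid),
            dsl=_parse_bool(row["dsl"], "dsl", sid),
            sublayer=bounds.sublayer(layer, depth),
            nutrients=nuts,
            water_mass=wm,
            omz=float(row["oxygen_mg_L"]) < omz_threshold,
        )
        info.validate(bounds)
        records.append(info)
    _check_ids([r.sample_id for r in records], "sample")
    return records


def metadata_frame(meta: list[SampleInfo]) -> pd.DataFrame:
    """Flatten SampleInfo records to a DataFrame (one row per sample)."""
    rows = []
    for m in meta:
        row = {
            "sample_id": m.sample_id, "station": m.station, "depth_m": m.depth_m,
            "layer": m.layer, "ocean": m.ocean, "template": m.template,
            "temperature_C": m.temperature_C, "salinity": m.salinity,
            "oxygen_mg_L": m.oxygen_mg_L, "light": m.light, "dsl": m.dsl,
            "sublayer": m.sublayer, "omz": m.omz,
        }
        for k, v in m.nutrients.items():
            row[f"nut_{k}"] = v
        for k, v in m.water_mass.items():
            row[f"wm_{k}"] = v
        rows.append(row)
    return pd.DataFrame(rows)


def write_metadata(meta: list[SampleInfo], path) -> None:
    df = metadata_frame(meta).drop(columns=["sublayer", "omz"])
    df["light"] = df["light"].map({True: "true", False: "false"})
    df["dsl"] = df["dsl"].map({True: "true", False: "false"})
    df.to_csv(path, sep="\t", index=False)


def read_taxonomy(path) -> list[TaxonAssignment]:
    df = pd.read_csv(path, sep="\t", header=0, dtype=str)
    for col in ("otu_id", "group"):
        if col not in df.columns:
            raise ValueError(f"taxonomy missing required column {col!r}")
    _check_ids(df["otu_id"], "OTU")
    out = []
    for _, row in df.iterrows():
        mode = row.get("trophic_mode", "unknown")
        if pd.isna(mode) or mode == "":
            mode = "unknown"
        out.append(TaxonAssignment(str(row["otu_id"]), str(row["group"]), str(mode)))
    return out


def write_taxonomy(tax: list[TaxonAssignment], path) -> None:
    pd.DataFrame(
        {
            "otu_id": [t.otu_id for t in tax],
            "group": [t.group for t in tax],
            "trophic_mode": [t.trophic_mode for t in tax],
        }
    ).to_csv(path, sep="\t", index=False)


# ---------------------------------------------------------------------------
# Operations
# ---------------------------------------------------------------------------

def rarefy(
    table: OtuTable,
    depth: int | None = None,
    seed: int = 0,
) -> OtuTable:
    """Subsample every sample to a common read depth, without replacement.

    Each column is drawn from a multivariate hypergeometric distribution
    (the per-read-without-replacement model behind vegan's ``rrarefy``), so
    retained columns sum to ``depth`` exactly.  Samples with fewer reads
    than ``depth`` are dropped with a warning; OTU rows left with no reads
    are removed.  Deterministic given ``seed``.

    ``depth`` defaults to the minimum column sum (the study convention of
    subsampling to the shallowest sample).
    """
    sums = table.column_sums()
    if depth is None:
        depth = int(sums.min())
    if depth <= 0:
        raise ValueError("rarefaction depth must be positive")
    keep = [s for s in table.sample_ids if sums[s] >= depth]
    dropped = [s for s in table.sample_ids if sums[s] < depth]
    if dropped:
        logger.warning(
            "rarefy: dropping %d sample(s) below depth %d: %s",
            len(dropped), depth, ", ".join(dropped),
        )
    if not keep:
        raise ValueError(f"all samples have fewer than {depth} reads")
    rng = np.random.default_rng(seed)
    counts = table.data[keep].to_numpy()
    out = np.empty_like(counts)
    for j in range(counts.shape[1]):
        col = counts[:, j]
        if col.sum() == depth:
            out[:, j] = col
        else:
            out[:, j] = rng.multivariate_hypergeometric(col, depth)
    result = OtuTable(pd.DataFrame(out, index=table.otu_ids, columns=keep))
    return result.drop_empty_otus()


def relative_abundance(table: OtuTable) -> RelAbundanceTable:
    """Counts -> per-sample proportions (columns sum to 1)."""
    counts = table.data.to_numpy(dtype=float)
    sums = counts.sum(axis=0)
    zero = np.where(sums == 0)[0]
    if zero.size:
        raise ValueError(f"sample {table.sample_ids[zero[0]]!r} has zero reads")
    return RelAbundanceTable(
        pd.DataFrame(counts / sums, index=table.otu_ids, columns=table.sample_ids)
    )


def split_by_template(
    table: OtuTable, meta: list[SampleInfo]
) -> tuple[OtuTable, OtuTable]:
    """Partition samples into (rDNA table, rRNA table) using metadata."""
    template = {m.sample_id: m.template for m in meta}
    missing = [s for s in table.sample_ids if s not in template]
    if missing:
        raise ValueError(f"sample(s) missing from metadata: {missing}")
    rdna = [s for s in table.sample_ids if template[s] == "rDNA"]
    rrna = [s for s in table.sample_ids if template[s] == "rRNA"]
    return (
        OtuTable(table.data[rdna]),
        OtuTable(table.data[rrna]),
    )


def taxonomy_map(tax: list[TaxonAssignment]) -> dict[str, str]:
    return {t.otu_id: t.group for t in tax}


def aggregate_by_group(table, tax: list[TaxonAssignment]) -> pd.DataFrame:
    """Sum rows of a count or relative-abundance table by taxonomic group.

    OTUs without an assignment are pooled under ``UNASSIGNED_GROUP``.
    Column totals are conserved exactly.
    """
    data = table.data if hasattr(table, "data") else pd.DataFrame(table)
    groups = taxonomy_map(tax)
    labels = [groups.get(o, UNASSIGNED_GROUP) for o in data.index]
    agg = data.groupby(pd.Index(labels, name="group"), sort=True).sum()
    return agg
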