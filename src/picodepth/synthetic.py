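"""Synthetic paired rDNA/rRNA amplicon survey generator.

Emulates a depth-stratified global-ocean picoeukaryote sampling design:
13 stations across three oceans, each profiled at seven depths spanning
surface, deep chlorophyll maximum (DCM), mesopelagic and bathypelagic
layers, sequenced from both DNA (rDNA) and RNA (rRNA) templates.

The generative model, per sample:

1. every taxonomic group follows a depth-response archetype (increase or
   decrease with depth, mesopelagic peak, DCM peak) that sets its expected
   cell mass per layer;
2. OTU masses within a group are log-normal around the group mass, with a
   per-station log-normal drift whose standard deviation grows with depth
   (distance decay widening in the dark ocean);
3. normalised masses give "cell" proportions pi;
4. rDNA read proportions are proportional to pi x copy_factor(group) —
   rDNA operon copy number inflates some clades (MALV-like);
5. rRNA read proportions are proportional to pi x activity_factor(group,
   layer) — the relative-activity signal;
6. oxygen-minimum-zone samples multiply designated groups' pi by an
   enrichment factor before templates are derived;
7. reads are drawn multinomially at a fixed depth per sample.

Everything is deterministic given the truth seed.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import yaml

from .core_tables import (
    LAYERS,
    LayerBounds,
    OtuTable,
    SampleInfo,
    TaxonAssignment,
)

ARCHETYPES = (
    "increase_with_depth",
    "decrease_with_depth",
    "meso_peak",
    "dcm_peak",
)

# Expected group mass per layer for each depth-response archetype.  The
# magnitudes are a modelling choice calibrated for testability (the source
# survey reports shapes, not effect sizes); they are configuration, not code.
ARCHETYPE_LAYER_WEIGHTS: dict[str, dict[str, float]] = {
    "increase_with_depth": {"surface": 0.3, "DCM": 0.5, "mesopelagic": 1.5, "bathypelagic": 3.0},
    "decrease_with_depth": {"surface": 3.0, "DCM": 2.0, "mesopelagic": 0.8, "bathypelagic": 0.2},
    "meso_peak": {"surface": 0.5, "DCM": 0.7, "mesopelagic": 3.0, "bathypelagic": 0.7},
    "dcm_peak": {"surface": 0.8, "DCM": 3.0, "mesopelagic": 0.5, "bathypelagic": 0.2},
}

#: Default group roster: (archetype, trophic mode).  Mirrors the named
#: groups of tropical/subtropical picoeukaryote surveys.
DEFAULT_GROUPS: dict[str, tuple[str, str]] = {
    "Chrysophyceae": ("increase_with_depth", "mixotrophic"),
    "Bicosoecida": ("increase_with_depth", "heterotrophic"),
    "RAD-B": ("increase_with_depth", "heterotrophic"),
    "Dinoflagellata": ("decrease_with_depth", "mixotrophic"),
    "Ciliophora": ("decrease_with_depth", "heterotrophic"),
    "MAST-3": ("decrease_with_depth", "heterotrophic"),
    "MAST-4": ("decrease_with_depth", "heterotrophic"),
    "MALV-I": ("meso_peak", "heterotrophic"),
    "MALV-II": ("meso_peak", "heterotrophic"),
    "MALV-III": ("meso_peak", "heterotrophic"),
    "Labyrinthulomycetes": ("meso_peak", "heterotrophic"),
    "RAD-C": ("meso_peak", "heterotrophic"),
    "Pelagophyceae": ("dcm_peak", "phototrophic"),
    "Mamiellophyceae": ("dcm_peak", "phototrophic"),
    "Cryptomonadales": ("dcm_peak", "phototrophic"),
    "Telonema": ("dcm_peak", "heterotrophic"),
}

#: rDNA operon copy-number multipliers; MALV-like clades are strongly
#: overrepresented in DNA surveys.
DEFAULT_COPY_FACTORS: dict[str, float] = {"MALV-I": 10.0, "MALV-II": 8.0}

#: Groups enriched inside the oxygen minimum zone, with their factors.
DEFAULT_OMZ_ENRICHMENT: dict[str, float] = {
    "Ciliophora": 4.0,
    "Dinoflagellata": 3.0,
    "MALV-III": 2.0,
}

#: Between-station compositional drift (log-normal sigma) per layer;
#: grows with depth so that horizontal dissimilarity widens downward.
DEFAULT_DECAY_RATES: dict[str, float] = {
    "surface": 0.3,
    "DCM": 0.4,
    "mesopelagic": 0.8,
    "bathypelagic": 1.3,
}

#: Log-normal sigma of OTU base masses within a group.  Amplicon OTU
#: abundance distributions are heavy-tailed (a few dominant OTUs, a long
#: rare tail); this dispersion makes most OTUs rare enough that detection
#: varies across stations, as in real surveys.
DEFAULT_OTU_SIGMA = 1.5

#: Default number of OTUs per group (9,600 in total with the default
#: roster).  Together with 25,000 reads per sample this puts typical OTUs
#: near the detection boundary, as in real surveys where the OTU count is
#: of the same order as the per-sample read count.
DEFAULT_OTUS_PER_GROUP = 600

#: Default station-depth grid: 7 depths covering the four layers.
DEFAULT_DEPTHS: tuple[tuple[float, str], ...] = (
    (3.0, "surface"),
    (80.0, "DCM"),
    (300.0, "mesopelagic"),
    (700.0, "mesopelagic"),
    (1500.0, "bathypelagic"),
    (2750.0, "bathypelagic"),
    (4000.0, "bathypelagic"),
)


def default_activity_factors(
    groups: dict[str, tuple[str, str]] | None = None,
) -> dict[tuple[str, str], float]:
    """Relative-activity multipliers per (group, layer).

    Heterotrophs peak in the mesopelagic (x3) and collapse in the
    bathypelagic (x0.3); phototrophs peak at the DCM (x2); mixotrophs stay
    active in the dark ocean (x2 in meso and bathy), the compositional
    counterweight that makes everyone else's bathypelagic hypoactivity
    visible in closed rRNA:rDNA ratios.
    """
    groups = DEFAULT_GROUPS if groups is None else groups
    factors: dict[tuple[str, str], float] = {}
    for g, (_, mode) in groups.items():
        for layer in LAYERS:
            factors[(g, layer)] = 1.0
        if mode == "heterotrophic":
            factors[(g, "mesopelagic")] = 3.0
            factors[(g, "bathypelagic")] = 0.3
        elif mode == "phototrophic":
            factors[(g, "DCM")] = 2.0
            factors[(g, "bathypelagic")] = 0.3
        elif mode == "mixotrophic":
            factors[(g, "mesopelagic")] = 2.0
            factors[(g, "bathypelagic")] = 2.0
    return factors


@dataclass
class SimTruth:
    """Generator parameters, kept for parameter-recovery tests."""

    group_profiles: dict[str, str]
    copy_factor: dict[str, float]
    activity_factor: dict[tuple[str, str], float]
    decay_rate: dict[str, float]
    omz_enrichment: dict[str, float]
    seed: int = 0

    def __post_init__(self):
        for g, a in self.group_profiles.items():
            if a not in ARCHETYPES:
                raise ValueError(f"group {g!r}: unknown archetype {a!r}")
        for name, mapping in (
            ("copy_factor", self.copy_factor),
            ("omz_enrichment", self.omz_enrichment),
        ):
            for k, v in mapping.items():
                if v <= 0:
                    raise ValueError(f"{name}[{k!r}] must be > 0")
        for k, v in self.activity_factor.items():
            if v <= 0:
                raise ValueError(f"activity_factor[{k!r}] must be > 0")


def default_truth(seed: int = 0) -> SimTruth:
    return SimTruth(
        group_profiles={g: arch for g, (arch, _) in DEFAULT_GROUPS.items()},
        copy_factor=dict(DEFAULT_COPY_FACTORS),
        activity_factor=default_activity_factors(),
        decay_rate=dict(DEFAULT_DECAY_RATES),
        omz_enrichment=dict(DEFAULT_OMZ_ENRICHMENT),
        seed=seed,
    )


def neutral_truth(seed: int = 0) -> SimTruth:
    """All multipliers 1 and zero drift: rDNA and rRNA differ only by
    multinomial noise.  Used for null-calibration tests."""
    truth = default_truth(seed)
    truth.copy_factor = {}
    truth.activity_factor = {k: 1.0 for k in truth.activity_factor}
    truth.decay_rate = {layer: 0.0 for layer in LAYERS}
    truth.omz_enrichment = {}
    return truth


@dataclass
class SimDesign:
    n_stations: int = 13
    depths_per_station: tuple[tuple[float, str], ...] = DEFAULT_DEPTHS
    oceans: dict[str, str] = field(default_factory=dict)
    reads_per_sample: int = 25_000
    n_otus_per_group: dict[str, int] = field(default_factory=dict)
    omz_stations: tuple[str, ...] = ()
    dsl_stations: tuple[str, ...] = ()

    def __post_init__(self):
        if self.reads_per_sample < 1_000:
            raise ValueError("reads_per_sample must be >= 1,000")

    @property
    def stations(self) -> list[str]:
        return [f"st{i + 1:02d}" for i in range(self.n_stations)]


def _station_oceans(stations: list[str]) -> dict[str, str]:
    # roughly even three-ocean split; the tail stations are Pacific so the
    # default OMZ stations fall in the Pacific.
    n = len(stations)
    third = max(1, n // 3)
    oceans = {}
    for i, st in enumerate(stations):
        if i < n - 2 * third:
            oceans[st] = "Atlantic"
        elif i < n - third:
            oceans[st] = "Indian"
        else:
            oceans[st] = "Pacific"
    return oceans


def make_design(
    n_stations: int = 13,
    depths: tuple[tuple[float, str], ...] = DEFAULT_DEPTHS,
    oceans: dict[str, str] | None = None,
    seed: int = 0,
    reads_per_sample: int = 25_000,
    n_otus_per_group: dict[str, int] | None = None,
    omz_stations: tuple[str, ...] | None = None,
    dsl_stations: tuple[str, ...] | None = None,
    bounds: LayerBounds = LayerBounds(),
) -> tuple[SimDesign, list[SampleInfo]]:
    """Build the sampling design and one SampleInfo per (station, depth,
    template).

    Defaults emulate the study design: 13 stations x 7 depths = 91
    station-depth samples, 4 Pacific stations hosting an oxygen minimum
    zone (low O2 at the two mesopelagic depths -> 8 OMZ samples) and a
    deep-scattering-layer flag at the upper mesopelagic depth of 9
    stations.  Environmental covariates are generated consistently with
    layer: light only in surface/DCM, temperature decreasing with depth,
    nutrients increasing, oxygen < 2 mg/L only at OMZ mesopelagic depths.
    """
    if n_stations < 2:
        raise ValueError("need at least 2 stations")
    if not depths:
        raise ValueError("empty depth list")
    layers_present = {layer for _, layer in depths}
    design = SimDesign(
        n_stations=n_stations,
        depths_per_station=tuple(depths),
        reads_per_sample=reads_per_sample,
        n_otus_per_group=(
            dict(n_otus_per_group)
            if n_otus_per_group is not None
            else {g: DEFAULT_OTUS_PER_GROUP for g in DEFAULT_GROUPS}
        ),
    )
    stations = design.stations
    design.oceans = dict(oceans) if oceans is not None else _station_oceans(stations)
    if omz_stations is None:
        pacific = [s for s in stations if design.oceans[s] == "Pacific"]
        omz_stations = tuple(pacific[-4:]) if "mesopelagic" in layers_present else ()
    if dsl_stations is None:
        dsl_stations = tuple(stations[2:11]) if "mesopelagic" in layers_present else ()
    design.omz_stations = tuple(omz_stations)
    design.dsl_stations = tuple(dsl_stations)

    rng = np.random.default_rng(seed)
    meta: list[SampleInfo] = []
    for st in stations:
        dsl_done = False
        for depth, layer in design.depths_per_station:
            light = layer in ("surface", "DCM")
            temp = 26.0 * np.exp(-depth / 350.0) + 2.0 + rng.normal(0, 0.4)
            sal = 35.0 + rng.normal(0, 0.2)
            omz_here = layer == "mesopelagic" and st in design.omz_stations
            if omz_here:
                oxygen = rng.uniform(0.4, 1.6)
            elif layer == "mesopelagic":
                oxygen = rng.uniform(3.0, 5.0)
            elif layer == "bathypelagic":
                oxygen = rng.uniform(4.5, 6.5)
            else:
                oxygen = rng.uniform(6.0, 7.5)
            dsl_here = (
                layer == "mesopelagic" and st in design.dsl_stations and not dsl_done
            )
            if dsl_here:
                dsl_done = True
            no3 = 36.0 * (1.0 - np.exp(-depth / 600.0)) + rng.uniform(0.0, 0.5)
            po4 = no3 / 16.0
            sio2 = 40.0 * (1.0 - np.exp(-depth / 900.0)) + rng.uniform(0.0, 0.5)
            if layer == "bathypelagic":
                f = rng.uniform(0.2, 0.8)
                wm = {"NADW": round(f, 6), "AABW": round(1.0 - f, 6)}
            elif layer == "mesopelagic":
                wm = {"AAIW": 1.0}
            else:
                wm = {"SURF": 1.0}
            for template in ("rDNA", "rRNA"):
                sid = f"{st}_d{int(depth):04d}_{template}"
                meta.append(
                    SampleInfo(
                        sample_id=sid,
                        station=st,
                        depth_m=depth,
                        layer=layer,
                        ocean=design.oceans[st],
                        template=template,
                        temperature_C=round(float(temp), 3),
                        salinity=round(float(sal), 3),
                        oxygen_mg_L=round(float(oxygen), 3),
                        light=light,
                        dsl=dsl_here,
                        sublayer=bounds.sublayer(layer, depth),
                        nutrients={
                            "NO3": round(float(no3), 3),
                            "PO4": round(float(po4), 4),
                            "SiO2": round(float(sio2), 3),
                        },
                        water_mass=wm,
                        omz=oxygen < 2.0,
                    )
                )
    for m in meta:
        m.validate(bounds)
    return design, meta


_LAYER_INDEX = {layer: i for i, layer in enumerate(LAYERS)}


def simulate_tables(
    design: SimDesign,
    truth: SimTruth,
) -> tuple[OtuTable, OtuTable, list[TaxonAssignment], SimTruth]:
    """Draw paired rDNA/rRNA count tables under the generative model."""
    groups = list(truth.group_profiles)
    if not groups:
        raise ValueError("truth defines no groups")
    n_per_group = [
        design.n_otus_per_group.get(g, DEFAULT_OTUS_PER_GROUP) for g in groups
    ]
    otu_ids: list[str] = []
    otu_group: list[str] = []
    for g, n in zip(groups, n_per_group):
        safe = g.replace(" ", "_")
        for i in range(n):
            otu_ids.append(f"{safe}_{i + 1:03d}")
            otu_group.append(g)
    n_otus = len(otu_ids)
    if n_otus == 0:
        raise ValueError("no OTUs to simulate")
    stations = design.stations
    st_index = {s: i for i, s in enumerate(stations)}

    rng = np.random.default_rng(truth.seed)
    base = rng.lognormal(mean=0.0, sigma=DEFAULT_OTU_SIGMA, size=n_otus)

    # layer weight per OTU: archetype response of its group
    layer_w = np.empty((n_otus, len(LAYERS)))
    for k, g in enumerate(otu_group):
        arch = truth.group_profiles[g]
        for layer, li in _LAYER_INDEX.items():
            layer_w[k, li] = ARCHETYPE_LAYER_WEIGHTS[arch][layer]

    # per-(otu, station, layer) compositional drift
    sigma = np.array([truth.decay_rate.get(layer, 0.0) for layer in LAYERS])
    z = rng.standard_normal((n_otus, len(stations), len(LAYERS)))
    drift = np.exp(z * sigma[None, None, :])

    copy = np.array([truth.copy_factor.get(g, 1.0) for g in otu_group])
    act = np.empty((n_otus, len(LAYERS)))
    for k, g in enumerate(otu_group):
        for layer, li in _LAYER_INDEX.items():
            act[k, li] = truth.activity_factor.get((g, layer), 1.0)
    omz_mult = np.array([truth.omz_enrichment.get(g, 1.0) for g in otu_group])

    # station-depth cells, one per metadata pair; rebuild sample grid
    sample_cols: dict[str, list[str]] = {"rDNA": [], "rRNA": []}
    rdna_counts = []
    rrna_counts = []
    for st in stations:
        for depth, layer in design.depths_per_station:
            li = _LAYER_INDEX[layer]
            mass = base * layer_w[:, li] * drift[:, st_index[st], li]
            omz_here = layer == "mesopelagic" and st in design.omz_stations
            if omz_here:
                mass = mass * omz_mult
            total = mass.sum()
            if total <= 0:
                raise ValueError("degenerate truth: all-zero masses")
            pi = mass / total
            p_dna = pi * copy
            p_dna /= p_dna.sum()
            p_rna = pi * act[:, li]
            p_rna /= p_rna.sum()
            rdna_counts.append(rng.multinomial(design.reads_per_sample, p_dna))
            rrna_counts.append(rng.multinomial(design.reads_per_sample, p_rna))
            sample_cols["rDNA"].append(f"{st}_d{int(depth):04d}_rDNA")
            sample_cols["rRNA"].append(f"{st}_d{int(depth):04d}_rRNA")

    rdna = OtuTable(
        pd.DataFrame(
            np.column_stack(rdna_counts), index=otu_ids, columns=sample_cols["rDNA"]
        )
    )
    rrna = OtuTable(
        pd.DataFrame(
            np.column_stack(rrna_counts), index=otu_ids, columns=sample_cols["rRNA"]
        )
    )
    mode = {g: DEFAULT_GROUPS.get(g, ("", "unknown"))[1] for g in groups}
    taxonomy = [
        TaxonAssignment(oid, g, mode.get(g, "unknown"))
        for oid, g in zip(otu_ids, otu_group)
    ]
    return rdna, rrna, taxonomy, truth


def simulate_tree(taxonomy: list[TaxonAssignment], seed: int = 0) -> str:
    """Random rooted binary tree whose tips are the OTUs, with every
    taxonomic group monophyletic (star-of-clades at the group level) and
    strictly positive branch lengths.  Returns a newick string."""
    if len(taxonomy) < 2:
        raise ValueError("need at least 2 OTUs")
    rng = np.random.default_rng(seed)

    def join_random(subtrees: list[str]) -> str:
        # random sequential pairing into a binary tree
        nodes = list(subtrees)
        while len(nodes) > 1:
            i, j = sorted(rng.choice(len(nodes), size=2, replace=False))
            right = nodes.pop(j)
            left = nodes.pop(i)
            bl_l = rng.uniform(0.05, 0.5)
            bl_r = rng.uniform(0.05, 0.5)
            nodes.append(f"({left}:{bl_l:.6f},{right}:{bl_r:.6f})")
        return nodes[0]

    by_group: dict[str, list[str]] = {}
    for t in taxonomy:
        by_group.setdefault(t.group, []).append(t.otu_id)
    clades = []
    for g in sorted(by_group):
        tips = by_group[g]
        clade = join_random(tips) if len(tips) > 1 else tips[0]
        clades.append(clade)
    if len(clades) == 1:
        return clades[0] + ";"
    return join_random(clades) + ";"


# ---------------------------------------------------------------------------
# Truth file I/O (YAML)
# ---------------------------------------------------------------------------

def write_truth(truth: SimTruth, path) -> None:
    payload = {
        "seed": int(truth.seed),
        "group_profiles": dict(truth.group_profiles),
        "copy_factor": {k: float(v) for k, v in truth.copy_factor.items()},
        "activity_factor": {
            f"{g}|{layer}": float(v)
            for (g, layer), v in sorted(truth.activity_factor.items())
        },
        "decay_rate": {k: float(v) for k, v in truth.decay_rate.items()},
        "omz_enrichment": {k: float(v) for k, v in truth.omz_enrichment.items()},
    }
    with open(path, "w", encoding="utf-8") as fh:
        yaml.safe_dump(payload, fh, sort_keys=True)


def read_truth(path) -> SimTruth:
    with open(path, encoding="utf-8") as fh:
        payload = yaml.safe_load(fh)
    act = {}
    for key, v in payload.get("activity_factor", {}).items():
        g, layer = key.split("|")
        act[(g, layer)] = float(v)
    return SimTruth(
        group_profiles=dict(payload["group_profiles"]),
        copy_factor={k: float(v) for k, v in payload.get("copy_factor", {}).items()},
        activity_factor=act,
        decay_rate={k: float(v) for k, v in payload.get("decay_rate", {}).items()},
        omz_enrichment={
            k: float(v) for k, v in payload.get("omz_enrichment", {}).items()
        },
        seed=int(payload.get("seed", 0)),
    )
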