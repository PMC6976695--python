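"""End-to-end orchestration: simulate a dataset to disk, or run the full
analysis (read -> rarefy -> split -> diversity -> activity -> biogeography
-> zones -> phylo) from TSV inputs, writing one TSV per stage plus a run
manifest that echoes every configured parameter.
"""

from __future__ import annotations

import json
import logging
from dataclasses import asdict, dataclass, fields
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import __version__
from . import activity as act_mod
from . import biogeography as bio_mod
from . import diversity as div_mod
from . import phylo as phy_mod
from . import synthetic as syn_mod
from . import zones as zon_mod
from .core_tables import (
    LAYERS,
    read_metadata,
    read_otu_table,
    read_taxonomy,
    relative_abundance,
    split_by_template,
    write_metadata,
    write_otu_table,
    write_taxonomy,
)

logger = logging.getLogger(__name__)

STAGES = (
    "read", "rarefy", "split", "diversity", "activity",
    "biogeography", "zones", "phylo",
)


class StageError(RuntimeError):
    def __init__(self, stage: str, cause: Exception):
        super().__init__(f"stage {stage!r} failed: {cause}")
        self.stage = stage
        self.cause = cause


@dataclass
class PipelineConfig:
    """Every knob of the pipeline; unknown keys in a config file are
    rejected.  All thresholds are echoed into the run manifest."""

    otu_table: str = ""
    metadata: str = ""
    taxonomy: str = ""
    tree: str = ""                      # optional; phylo skipped when empty
    output_dir: str = "picodepth_out"
    rarefaction_depth: int | None = None   # None = minimum column sum
    rarefaction_seed: int = 0
    omz_threshold: float = 2.0
    activity_band: tuple[float, float] = (0.5, 2.0)
    alpha: float = 0.05
    share_threshold: float = 0.0005
    gunifrac_alpha: float = 0.5
    min_restricted_reads: int = 5
    prevalence_q: float = 0.8
    anosim_permutations: int = 1000
    permanova_permutations: int = 999
    nmds_starts: int = 20
    seed: int = 0
    # simulation-only knobs
    sim_stations: int = 13
    sim_reads_per_sample: int = 25_000
    sim_otus_per_group: int = 600

    @classmethod
    def from_yaml(cls, path) -> "PipelineConfig":
        with open(path, encoding="utf-8") as fh:
            payload = yaml.safe_load(fh) or {}
        known = {f.name for f in fields(cls)}
        unknown = set(payload) - known
        if unknown:
            raise ValueError(f"unknown config key(s): {sorted(unknown)}")
        if "activity_band" in payload:
            payload["activity_band"] = tuple(payload["activity_band"])
        return cls(**payload)


def simulate_command(config: PipelineConfig) -> dict:
    """Write a synthetic paired dataset (tables, metadata, taxonomy, tree,
    truth file) under ``config.output_dir``."""
    out = Path(config.output_dir)
    out.mkdir(parents=True, exist_ok=True)
    design, meta = syn_mod.make_design(
        n_stations=config.sim_stations,
        seed=config.seed,
        reads_per_sample=config.sim_reads_per_sample,
        n_otus_per_group={g: config.sim_otus_per_group for g in syn_mod.DEFAULT_GROUPS},
    )
    truth = syn_mod.default_truth(seed=config.seed)
    rdna, rrna, taxonomy, truth = syn_mod.simulate_tables(design, truth)
    combined = pd.concat([rdna.data, rrna.data], axis=1)
    combined.to_csv(out / "otu_table.tsv", sep="\t", index_label="otu_id")
    write_metadata(meta, out / "metadata.tsv")
    write_taxonomy(taxonomy, out / "taxonomy.tsv")
    (out / "tree.nwk").write_text(
        syn_mod.simulate_tree(taxonomy, seed=config.seed), encoding="utf-8"
    )
    syn_mod.write_truth(truth, out / "truth.yaml")
    manifest = {
        "command": "simulate",
        "version": __version__,
        "seed": config.seed,
        "n_stations": design.n_stations,
        "station_depth_samples": design.n_stations * len(design.depths_per_station),
        "reads_per_sample": design.reads_per_sample,
        "files": [
            "otu_table.tsv", "metadata.tsv", "taxonomy.tsv", "tree.nwk", "truth.yaml",
        ],
    }
    (out / "manifest.json").write_text(
        json.dumps(manifest, indent=2, sort_keys=True) + "\n", encoding="utf-8"
    )
    return manifest


def _write_tsv(df: pd.DataFrame, path: Path, header_lines: list[str]) -> None:
    with open(path, "w", encoding="utf-8") as fh:
        for line in header_lines:
            fh.write(f"# {line}\n")
        df.to_csv(fh, sep="\t", float_format="%.10g")


def run_pipeline(config: PipelineConfig) -> dict:
    """Run every analysis stage in order; abort naming the failing stage.

    Returns the manifest (also written to ``output_dir/manifest.json``).
    Deterministic — byte-identical outputs — for a fixed config.
    """
    out = Path(config.output_dir)
    out.mkdir(parents=True, exist_ok=True)
    completed: list[str] = []
    echo = [
        f"picodepth {__version__}",
        f"omz_threshold={config.omz_threshold}",
        f"activity_band={config.activity_band}",
        f"alpha={config.alpha}",
        f"share_threshold={config.share_threshold}",
        f"gunifrac_alpha={config.gunifrac_alpha}",
        f"rarefaction_seed={config.rarefaction_seed}",
        f"seed={config.seed}",
    ]

    def stage(name: str):
        class _Ctx:
            def __enter__(self):
                logger.info("[%s] start", name)

            def __exit__(self, exc_type, exc, tb):
                if exc is not None:
                    raise StageError(name, exc) from exc
                completed.append(name)
                logger.info("[%s] done", name)

        return _Ctx()

    with stage("read"):
        table = read_otu_table(config.otu_table)
        meta = read_metadata(config.metadata, omz_threshold=config.omz_threshold)
        tax = read_taxonomy(config.taxonomy)
        tree = None
        if config.tree and Path(config.tree).exists():
            tree = phy_mod.read_newick(config.tree)

    with stage("rarefy"):
        from .core_tables import rarefy as _rarefy
        rarefied = _rarefy(
            table, depth=config.rarefaction_depth, seed=config.rarefaction_seed
        )
        depth_used = int(rarefied.column_sums().iloc[0])
        write_otu_table(rarefied, out / "rarefied_table.tsv")

    with stage("split"):
        meta = [m for m in meta if m.sample_id in set(rarefied.sample_ids)]
        rdna, rrna = split_by_template(rarefied, meta)
        rdna_rel = relative_abundance(rdna.drop_empty_otus())
        rrna_rel = relative_abundance(rrna.drop_empty_otus())

    meta_by_template = {
        "rDNA": [m for m in meta if m.template == "rDNA"],
        "rRNA": [m for m in meta if m.template == "rRNA"],
    }

    with stage("diversity"):
        alpha_rows = []
        for m in meta:
            if m.sample_id not in rarefied.sample_ids:
                continue
            col = rarefied.data[m.sample_id]
            alpha_rows.append(
                {
                    "sample_id": m.sample_id,
                    "template": m.template,
                    "layer": m.layer,
                    "shannon": div_mod.shannon(col),
                    "richness": div_mod.richness(col),
                }
            )
        _write_tsv(
            pd.DataFrame(alpha_rows).set_index("sample_id"),
            out / "alpha_diversity.tsv",
            echo,
        )
        div_results = {}
        for name, tab, mlist in (
            ("rDNA", rdna, meta_by_template["rDNA"]),
            ("rRNA", rrna, meta_by_template["rRNA"]),
        ):
            if tab.shape[1] < 3:
                continue
            dm = div_mod.bray_curtis(tab)
            pd.DataFrame(dm.data, index=dm.ids, columns=dm.ids).to_csv(
                out / f"bray_curtis_{name}.tsv", sep="\t", float_format="%.10g"
            )
            info = {m.sample_id: m for m in mlist}
            photic = np.array(
                ["photic" if info[s].light else "aphotic" for s in dm.ids]
            )
            res = div_mod.anosim(
                dm, photic, n_perm=config.anosim_permutations, seed=config.seed
            )
            emb = div_mod.nmds(
                dm, k=2, n_starts=config.nmds_starts, seed=config.seed
            )
            coords = emb.coordinates.copy()
            _write_tsv(
                coords,
                out / f"nmds_{name}.tsv",
                echo + [f"stress={emb.stress:.6g}"],
            )
            terms = pd.DataFrame(
                {
                    "light": [info[s].light for s in dm.ids],
                    "temperature_C": [info[s].temperature_C for s in dm.ids],
                    "oxygen_mg_L": [info[s].oxygen_mg_L for s in dm.ids],
                    "ocean": [info[s].ocean for s in dm.ids],
                    "depth_m": [info[s].depth_m for s in dm.ids],
                }
            )
            perma = div_mod.permanova(
                dm, terms, n_perm=config.permanova_permutations, seed=config.seed
            )
            _write_tsv(perma.table, out / f"permanova_{name}.tsv", echo)
            div_results[name] = {
                "anosim_R": res.statistic,
                "anosim_p": res.p_value,
                "nmds_stress": emb.stress,
            }

    with stage("activity"):
        pairs = act_mod.pair_samples(meta)
        records = act_mod.activity_ratios(rdna_rel, rrna_rel, pairs, tax)
        rec_df = act_mod.records_frame(records)
        rec_df["class"] = [
            act_mod.classify_activity(r, config.activity_band) for r in rec_df["ratio"]
        ]
        _write_tsv(rec_df.set_index("otu_id"), out / "activity_records.tsv", echo)
        contrasts = act_mod.layer_contrasts(records, alpha=config.alpha)
        c_rows = []
        for c in contrasts:
            row = {"group": c.group}
            for layer in LAYERS:
                row[f"median_{layer}"] = c.layer_medians.get(layer, np.nan)
            row["significantly_high"] = ",".join(sorted(c.significantly_high))
            row["significantly_low"] = ",".join(sorted(c.significantly_low))
            for (a, b), p in sorted(c.pairwise_p.items()):
                row[f"p_{a}_vs_{b}"] = p
                row[f"padj_{a}_vs_{b}"] = c.pairwise_p_adjusted[(a, b)]
            c_rows.append(row)
        _write_tsv(
            pd.DataFrame(c_rows).set_index("group"),
            out / "layer_contrasts.tsv",
            echo,
        )
        assignments = act_mod.layer_of_max_activity(records)

    with stage("biogeography"):
        bio_tables = []
        for name, tab, mlist in (
            ("rDNA", rdna, meta_by_template["rDNA"]),
            ("rRNA", rrna, meta_by_template["rRNA"]),
        ):
            dm = div_mod.bray_curtis(tab)
            dists = bio_mod.layer_dissimilarity_distributions(dm, mlist, "sublayer")
            rows = [
                {"template": name, "stratum": k, "n_pairs": len(v),
                 "median_bray_curtis": float(np.median(v))}
                for k, v in sorted(dists.items())
            ]
            bio_tables.extend(rows)
            for layer in LAYERS:
                curve = bio_mod.prevalence_curves(
                    tab, mlist, layer, q=config.prevalence_q
                )
                _write_tsv(
                    pd.DataFrame(
                        {"n_stations": list(curve.counts),
                         "n_otus": list(curve.counts.values())}
                    ).set_index("n_stations"),
                    out / f"prevalence_{name}_{layer}.tsv",
                    echo + [f"fraction_prevalent_q{config.prevalence_q}="
                            f"{curve.fraction_prevalent:.6g}"],
                )
            restricted = bio_mod.layer_restricted_otus(
                tab, mlist, min_reads=config.min_restricted_reads
            )
            _write_tsv(
                pd.DataFrame(
                    {
                        "layer": list(LAYERS),
                        "n_restricted": [len(restricted[l][0]) for l in LAYERS],
                        "fraction": [restricted[l][1] for l in LAYERS],
                    }
                ).set_index("layer"),
                out / f"restricted_otus_{name}.tsv",
                echo + [f"min_reads>{config.min_restricted_reads}"],
            )
            shared = bio_mod.shared_otu_matrix(tab, mlist)
            _write_tsv(shared, out / f"shared_otus_{name}.tsv", echo)
        _write_tsv(
            pd.DataFrame(bio_tables).set_index(["template", "stratum"]),
            out / "layer_dissimilarity_medians.tsv",
            echo,
        )

    with stage("zones"):
        zone_rows = []
        richness_rows = []
        for zone in ("OMZ", "DSL"):
            try:
                split = zon_mod.define_zone(meta_by_template["rRNA"], zone)
            except ValueError as exc:
                logger.warning("zones: %s skipped (%s)", zone, exc)
                continue
            contr = zon_mod.zone_contrast(
                rrna_rel, records, tax, split,
                share_threshold=config.share_threshold,
            )
            for c in contr:
                zone_rows.append(
                    {
                        "zone": zone,
                        "group": c.group,
                        "mesopelagic_share": c.mesopelagic_share,
                        "abundance_ratio": c.abundance_ratio,
                        "activity_ratio": c.activity_ratio,
                        "reason": c.reason,
                    }
                )
            rc = zon_mod.zone_richness_contrast(rrna, split)
            richness_rows.append(
                {
                    "zone": zone,
                    "zone_median_richness": rc.zone_median,
                    "complement_median_richness": rc.complement_median,
                    "p_value": rc.p_value,
                    "n_zone": rc.n_zone,
                    "n_complement": rc.n_complement,
                }
            )
        if zone_rows:
            _write_tsv(
                pd.DataFrame(zone_rows).set_index(["zone", "group"]),
                out / "zone_contrasts.tsv",
                echo,
            )
        if richness_rows:
            _write_tsv(
                pd.DataFrame(richness_rows).set_index("zone"),
                out / "zone_richness.tsv",
                echo,
            )

    if tree is not None:
        with stage("phylo"):
            sets = act_mod.layer_sets(assignments)
            vectors = phy_mod.normalized_layer_vectors(
                rrna_rel, meta_by_template["rRNA"], sets
            )
            if len(vectors) >= 2:
                mat = phy_mod.layer_phylo_distances(
                    tree, vectors, alpha=config.gunifrac_alpha
                )
                _write_tsv(mat, out / "layer_gunifrac.tsv", echo)
            else:
                logger.warning("phylo: fewer than 2 non-empty layer sets; matrix skipped")
    elif config.tree:
        raise StageError("phylo", FileNotFoundError(config.tree))

    manifest = {
        "command": "run-all",
        "version": __version__,
        "completed_stages": completed,
        "rarefaction_depth": depth_used,
        "config": {
            k: (list(v) if isinstance(v, tuple) else v)
            for k, v in asdict(config).items()
        },
        "diversity": div_results,
        "n_activity_records": len(rec_df),
        "n_otus_in_all_layers": len(assignments),
    }
    (out / "manifest.json").write_text(
        json.dumps(manifest, indent=2, sort_keys=True) + "\n", encoding="utf-8"
    )
    return manifest
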