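"""End-to-end orchestration: filter -> diversity -> frequencies ->
relatedness -> de-duplication -> UPGMA families -> spatial tests.

Every stage writes its intermediate to the output directory and the report
records seeds, thresholds and all headline numbers, so each reported value is
recomputable from the written intermediates.
"""

from __future__ import annotations

import json
import time
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import __version__
from .diversity import fis_weir_cockerham, hwe_exact_test, locus_summary, summary_frame
from .families import (
    annotate,
    distance_from_relatedness,
    extract_families,
    family_summary,
    to_newick,
    upgma,
)
from .io import (
    GenotypeMatrix,
    SampleMetadata,
    filter_by_amplification,
    read_genotypes,
    read_metadata,
    write_genotypes,
)
from .relatedness import estimate_frequencies_em, ml_relatedness, remove_duplicates
from .simulate import SimulationConfig, simulate_population
from .spatial import (
    RelatednessClassSpec,
    bootstrap_balanced_kw,
    class_counts,
    classify_pairs,
    family_dispersion_test,
    pairwise_distances,
)


def pair_count(n: int) -> int:
    """Number of unordered pairs among n individuals; 0 for n < 2."""
    if n < 2:
        return 0
    return n * (n - 1) // 2


@dataclass
class PipelineConfig:
    """Inputs, thresholds and per-stage seeds of one pipeline run.

    Either ``genotypes``/``metadata`` paths or a ``simulate`` block must be
    given. The constants default to the analysis constants: 75% minimal
    amplification success, duplicate threshold r > 0.95, family threshold
    rbar_N >= 0.25, balanced bootstrap R = 1000.
    """

    out_dir: str | Path
    genotypes: str | Path | None = None
    metadata: str | Path | None = None
    dialect: str = "genalex_csv"
    simulate: SimulationConfig | None = None
    min_success: float = 0.75
    duplicate_threshold: float = 0.95
    family_threshold: float = 0.25
    class_edges: tuple[float, ...] = (0.0, 0.0625, 0.125, 0.25, 0.5, 0.6, 0.75, 1.0)
    bootstrap_R: int = 1000
    hwe_n_mc: int = 10_000
    fis_n_perm: int = 0
    null_em: bool = True
    seed: int = 1
    n_perm_dispersion: int = 999

    def __post_init__(self) -> None:
        if (self.genotypes is None) == (self.simulate is None):
            raise ValueError("provide either input paths or a simulation block")
        for name in ("min_success", "duplicate_threshold", "family_threshold"):
            v = getattr(self, name)
            if not 0 < v <= 1:
                raise ValueError(f"{name} must be in (0, 1]")
        if self.bootstrap_R < 1:
            raise ValueError("bootstrap_R must be >= 1")

    @classmethod
    def from_yaml(cls, path: str | Path) -> "PipelineConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh)
        if "simulate" in raw and raw["simulate"] is not None:
            sim = raw["simulate"]
            if "family_spec" in sim:
                sim["family_spec"] = tuple(tuple(t) for t in sim["family_spec"])
            if isinstance(sim.get("alleles_per_locus"), list):
                sim["alleles_per_locus"] = tuple(sim["alleles_per_locus"])
            if "arena" in sim:
                sim["arena"] = tuple(sim["arena"])
            raw["simulate"] = SimulationConfig(**sim)
        if "class_edges" in raw:
            raw["class_edges"] = tuple(raw["class_edges"])
        return cls(**raw)


def run_pipeline(config: PipelineConfig) -> dict:
    """Run every stage in order and return the report dictionary.

    Stage order: filter -> diversity -> frequency estimation -> pairwise ML
    relatedness -> duplicate removal -> UPGMA family extraction -> spatial
    class tests and family dispersion. All intermediates are written under
    ``config.out_dir``; the JSON report is written there too.
    """
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    report: dict = {
        "version": __version__,
        "seed": config.seed,
        "thresholds": {
            "min_success": config.min_success,
            "duplicate_threshold": config.duplicate_threshold,
            "family_threshold": config.family_threshold,
            "class_edges": list(config.class_edges),
            "bootstrap_R": config.bootstrap_R,
        },
        "stages": {},
    }
    rng = np.random.default_rng(config.seed)
    stage_seeds = {
        name: int(s)
        for name, s in zip(
            ("hwe", "fis", "bootstrap", "dispersion"),
            rng.integers(0, 2**31 - 1, size=4),
        )
    }
    report["stage_seeds"] = stage_seeds

    def stage(name):
        t0 = time.perf_counter()

        def done(**numbers):
            report["stages"][name] = {
                "wall_s": round(time.perf_counter() - t0, 3),
                **numbers,
            }

        return done

    # -- inputs
    done = stage("input")
    if config.simulate is not None:
        gm, meta, truth = simulate_population(config.simulate)
        write_genotypes(gm, out / "genotypes_raw.csv", config.dialect)
        meta.table.to_csv(out / "metadata.csv", index_label="id")
        dyads, fams = truth.to_frames()
        dyads.to_csv(out / "truth_dyads.csv", index=False)
        fams.to_csv(out / "truth_families.csv", index=False)
    else:
        gm = read_genotypes(config.genotypes, config.dialect)
        meta = read_metadata(config.metadata) if config.metadata else None
        truth = None
    done(n_individuals=gm.n_individuals, n_loci=gm.n_loci)

    # -- amplification filter
    done = stage("filter")
    gm_f, removed = filter_by_amplification(gm, config.min_success)
    write_genotypes(gm_f, out / "genotypes_filtered.csv", config.dialect)
    done(retained=gm_f.n_individuals, removed=len(removed))

    # -- diversity
    done = stage("diversity")
    summaries = locus_summary(gm_f)
    for s in summaries:
        s.hwe_p = hwe_exact_test(gm_f, s.locus, config.hwe_n_mc, stage_seeds["hwe"])
    fis_per_locus, fis_multi, fis_p = fis_weir_cockerham(
        gm_f, config.fis_n_perm, stage_seeds["fis"]
    )
    for s in summaries:
        s.Fis = fis_per_locus.get(s.locus)
    df = summary_frame(summaries)
    df.to_csv(out / "diversity.tsv", sep="\t")
    done(
        mean_Na=float(df["Na"].mean()),
        mean_Ho=float(df["Ho"].mean()),
        mean_He=float(df["He"].mean()),
        multilocus_Fis=float(fis_multi),
        Fis_p=fis_p,
    )

    # -- frequencies + relatedness
    done = stage("relatedness")
    freqs = estimate_frequencies_em(gm_f, with_null=config.null_em)
    pd.DataFrame(
        {
            "locus": [lf.locus for lf in freqs],
            "null_freq": [lf.null_freq for lf in freqs],
        }
    ).to_csv(out / "null_freqs.tsv", sep="\t", index=False)
    rm = ml_relatedness(gm_f, freqs)
    cond = rm.condensed()
    finite = cond[np.isfinite(cond)]
    long = classify_pairs(rm, RelatednessClassSpec(config.class_edges))
    long[["id1", "id2", "r"]].assign(
        n_loci=rm.n_loci[np.triu_indices(rm.n, 1)][np.isfinite(cond)]
    ).to_csv(out / "relatedness_pairs.tsv", sep="\t", index=False)
    done(
        n_pairs=pair_count(gm_f.n_individuals),
        pct_r_above_025=100.0 * float(np.mean(finite > 0.25)),
        pct_r_above_05=100.0 * float(np.mean(finite > 0.5)),
        n_r_above_075=int(np.sum(finite > 0.75)),
    )

    # -- duplicate removal
    done = stage("deduplicate")
    retained, dup_pairs = remove_duplicates(rm, gm_f, config.duplicate_threshold)
    rm_d = rm.subset(retained)
    done(duplicate_pairs=len(dup_pairs), retained=len(retained))

    # -- UPGMA families
    done = stage("families")
    root = upgma(distance_from_relatedness(rm_d))
    annotate(root, rm_d)
    fa = extract_families(root, rm_d, config.family_threshold)
    fam_rows = [
        {"id": m, "family": fam}
        for fam, members in fa.families.items()
        for m in members
    ] + [{"id": s, "family": ""} for s in fa.singletons]
    pd.DataFrame(fam_rows).to_csv(out / "families.tsv", sep="\t", index=False)
    (out / "dendrogram.nwk").write_text(to_newick(root, rm_d.ids))
    fam_stats = family_summary(fa, rm_d)
    done(
        n_families=fam_stats["n_families"],
        largest_family=fam_stats["size_max"],
        pct_in_families=fam_stats["pct_in_families"],
        n_families_gt3=fam_stats["n_families_gt3"],
        mean_within_family_r=fam_stats["mean_within_family_r"],
    )

    # -- spatial
    if meta is not None:
        done = stage("spatial")
        meta_d = meta.subset(rm_d.ids)
        dist = pairwise_distances(meta_d)
        spec = RelatednessClassSpec(config.class_edges)
        pairs = classify_pairs(rm_d, spec)
        counts = class_counts(pairs, spec)
        pair_dist = dist[pairs["i"].to_numpy(), pairs["j"].to_numpy()]
        boot = bootstrap_balanced_kw(
            pair_dist,
            pairs["class_index"].to_numpy(),
            R=config.bootstrap_R,
            seed=stage_seeds["bootstrap"],
            class_labels=spec.labels(),
        )
        if boot.dunn_median_p is not None:
            boot.dunn_median_p.to_csv(out / "dunn_median_p.tsv", sep="\t")
        disp_obs = disp_null = disp_p = None
        if fa.families:
            disp_obs, disp_null, disp_p = family_dispersion_test(
                fa, dist, rm_d.ids, config.n_perm_dispersion,
                stage_seeds["dispersion"],
            )
        done(
            class_counts=counts.to_dict(),
            min_class_size=boot.min_class_size,
            median_p=boot.median_p,
            p_ci=list(boot.p_ci),
            significant=boot.significant,
            dispersion_observed_km=disp_obs,
            dispersion_null_km=disp_null,
            dispersion_p=disp_p,
        )

    with open(out / "report.json", "w") as fh:
        json.dump(report, fh, indent=2, default=float)
    return report
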