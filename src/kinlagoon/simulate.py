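"""Synthetic pedigreed microsatellite genotypes with known truth.

Generates founder genotypes from Hardy-Weinberg proportions at Dirichlet-drawn
allele frequencies, embeds parent-offspring (PO), full-sib (FS) and half-sib
(HS) families in an unrelated background, applies a per-locus null allele and
per-cell missingness, duplicates a configurable number of samples (field
re-captures), and scatters family members around spatial anchors inside a
lagoon-scale arena. Ground truth (dyad relationships, family labels, true
frequencies) is returned alongside, so every downstream stage of the pipeline
can be validated without real data.

The null-allele mechanism is one designated invisible allele per locus: a
visible/null heterozygote is scored as an apparent homozygote, a null
homozygote as missing. Loci are unlinked; no mutation or selection.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np
import yaml

from .io import MISSING, GenotypeMatrix, SampleMetadata
from .relatedness import NULL, LocusFrequencies

import pandas as pd

#: IBD-mode probabilities (k0, k1, k2) for the supported dyad relationships
K_COEFFICIENTS = {
    "U": (1.0, 0.0, 0.0),
    "HS": (0.5, 0.5, 0.0),
    "PO": (0.0, 1.0, 0.0),
    "FS": (0.25, 0.5, 0.25),
}

#: km per degree of latitude on a sphere of mean radius 6371.0088 km
KM_PER_DEG = 111.19492664455873

#: Bora-Bora-like lagoon bounding box (lat_min, lat_max, lon_min, lon_max),
#: roughly 10 x 10 km
DEFAULT_ARENA = (-16.55, -16.46, -151.79, -151.70)


@dataclass
class SimulationConfig:
    """Parameters of one synthetic population.

    ``family_spec`` lists (relationship, family_size, n_families) triples with
    relationship in {PO, FS, HS} and family_size the number of *sampled*
    members. FS families are full sibships (two latent parents); HS families
    share exactly one latent parent; a PO family samples one parent plus its
    offspring by distinct latent mates (so sampled offspring pairs are HS).
    ``alleles_per_locus`` is a fixed count or an inclusive (low, high) range.
    ``freq_concentration`` is the symmetric Dirichlet concentration per
    allele; the default 0.265 yields mean expected heterozygosity near 0.67
    for 4-21 alleles per locus. Rates default to 0.05 for both the per-locus
    null allele and per-cell missingness. ``kin_sigma_km`` is the isotropic
    scatter of family members around their family anchor.
    """

    seed: int
    n_loci: int = 21
    alleles_per_locus: int | tuple[int, int] = (4, 21)
    freq_concentration: float = 0.265
    family_spec: tuple[tuple[str, int, int], ...] = ()
    n_unrelated: int = 50
    null_rate_per_locus: float = 0.05
    missing_rate: float = 0.05
    n_duplicates: int = 0
    kin_sigma_km: float = 1.0
    arena: tuple[float, float, float, float] = DEFAULT_ARENA
    motif_step: int = 3

    def __post_init__(self) -> None:
        if self.n_loci < 1:
            raise ValueError("n_loci must be >= 1")
        lo, hi = self.allele_range()
        if lo < 2 or hi < lo:
            raise ValueError("alleles_per_locus must be >= 2 (and a valid range)")
        for rate, name in (
            (self.null_rate_per_locus, "null_rate_per_locus"),
            (self.missing_rate, "missing_rate"),
        ):
            if not 0 <= rate <= 1:
                raise ValueError(f"{name} must be in [0, 1]")
        if self.null_rate_per_locus >= 1:
            raise ValueError("null_rate_per_locus must be < 1")
        self.family_spec = tuple(
            (str(rel), int(size), int(count)) for rel, size, count in self.family_spec
        )
        for rel, size, count in self.family_spec:
            if rel not in ("PO", "FS", "HS"):
                raise ValueError(f"unknown relationship {rel!r} in family_spec")
            if size < 2:
                raise ValueError("family_size must be >= 2")
            if count < 0:
                raise ValueError("n_families must be >= 0")
        if self.n_unrelated < 0 or self.n_duplicates < 0:
            raise ValueError("counts must be >= 0")
        if self.kin_sigma_km <= 0:
            raise ValueError("kin_sigma_km must be positive")
        lat0, lat1, lon0, lon1 = self.arena
        if not (lat0 < lat1 and lon0 < lon1):
            raise ValueError("arena must be (lat_min, lat_max, lon_min, lon_max)")
        n_sampled = self.n_unrelated + sum(s * c for _, s, c in self.family_spec)
        if n_sampled == 0:
            raise ValueError("configuration samples no individuals")
        if self.n_duplicates > n_sampled:
            raise ValueError("more duplicates requested than individuals simulated")

    def allele_range(self) -> tuple[int, int]:
        if isinstance(self.alleles_per_locus, int):
            return self.alleles_per_locus, self.alleles_per_locus
        lo, hi = self.alleles_per_locus
        return int(lo), int(hi)

    @classmethod
    def from_yaml(cls, path: str | Path) -> "SimulationConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh)
        if "seed" not in raw:
            raise ValueError("simulation config requires an explicit seed")
        if "family_spec" in raw:
            raw["family_spec"] = tuple(tuple(t) for t in raw["family_spec"])
        if "alleles_per_locus" in raw and isinstance(raw["alleles_per_locus"], list):
            raw["alleles_per_locus"] = tuple(raw["alleles_per_locus"])
        if "arena" in raw:
            raw["arena"] = tuple(raw["arena"])
        return cls(**raw)

    def to_yaml(self, path: str | Path) -> None:
        data = {
            "seed": self.seed,
            "n_loci": self.n_loci,
            "alleles_per_locus": list(self.allele_range()),
            "freq_concentration": self.freq_concentration,
            "family_spec": [list(t) for t in self.family_spec],
            "n_unrelated": self.n_unrelated,
            "null_rate_per_locus": self.null_rate_per_locus,
            "missing_rate": self.missing_rate,
            "n_duplicates": self.n_duplicates,
            "kin_sigma_km": self.kin_sigma_km,
            "arena": list(self.arena),
            "motif_step": self.motif_step,
        }
        with open(path, "w") as fh:
            yaml.safe_dump(data, fh, sort_keys=False)


@dataclass
class TruthTables:
    """Ground truth of one simulated population.

    ``dyad_relationship`` holds only non-U pairs, keyed by sorted id pairs;
    ``family_label`` maps every sampled individual to its family id or None.
    """

    dyad_relationship: dict[tuple[str, str], str]
    family_label: dict[str, str | None]
    true_null_freq: dict[str, float]
    true_allele_freqs: dict[str, LocusFrequencies]

    def relationship(self, id1: str, id2: str) -> str:
        return self.dyad_relationship.get(tuple(sorted((id1, id2))), "U")

    def family_vector(self, ids: Sequence[str]) -> list[str]:
        """Partition labels for external-index comparison; singletons unique."""
        return [
            self.family_label[s] if self.family_label[s] is not None else f"_solo_{s}"
            for s in ids
        ]

    def to_frames(self) -> tuple[pd.DataFrame, pd.DataFrame]:
        dyads = pd.DataFrame(
            [(a, b, rel) for (a, b), rel in sorted(self.dyad_relationship.items())],
            columns=["id1", "id2", "relationship"],
        )
        fams = pd.DataFrame(
            [(s, lab if lab is not None else "") for s, lab in self.family_label.items()],
            columns=["id", "family"],
        )
        return dyads, fams


# -- allele frequencies -----------------------------------------------------


def generate_allele_frequencies(
    n_loci: int,
    alleles_per_locus: int | tuple[int, int],
    concentration: float,
    seed: int | np.random.Generator,
    motif_step: int = 3,
) -> list[LocusFrequencies]:
    """Dirichlet visible-allele frequencies for ``n_loci`` unlinked loci.

    Allele labels are fragment sizes on a repeat-motif ladder (configurable
    step). ``concentration`` is the per-allele symmetric Dirichlet parameter;
    ``inf`` gives exactly equal frequencies. Frequencies sum to 1 per locus.
    """
    if n_loci < 1:
        raise ValueError("n_loci must be >= 1")
    rng = np.random.default_rng(seed) if not isinstance(seed, np.random.Generator) else seed
    if isinstance(alleles_per_locus, int):
        lo = hi = alleles_per_locus
    else:
        lo, hi = alleles_per_locus
    if lo < 2:
        raise ValueError("alleles_per_locus must be >= 2")
    out = []
    for j in range(n_loci):
        K = int(rng.integers(lo, hi + 1))
        base = int(rng.integers(80, 301))
        labels = base + motif_step * np.arange(K)
        if np.isinf(concentration):
            p = np.full(K, 1.0 / K)
        else:
            if concentration <= 0:
                raise ValueError("concentration must be positive")
            p = rng.dirichlet(np.full(K, concentration))
            # a numerically zero class would make the label unobservable and
            # later frequency lookups ill-posed; keep a floor and renormalise
            p = np.maximum(p, 1e-9)
            p /= p.sum()
        out.append(LocusFrequencies(f"L{j + 1:02d}", labels, p, 0.0))
    return out


def paper_like_frequencies(seed: int, n_loci: int = 21) -> list[LocusFrequencies]:
    """Frequencies emulating a diverse microsatellite panel: 4-21 alleles per
    locus and mean expected heterozygosity near 0.67."""
    return generate_allele_frequencies(n_loci, (4, 21), 0.265, seed)


def _with_null(freqs: Sequence[LocusFrequencies], null_rate: float) -> list[LocusFrequencies]:
    """Rescale visible frequencies to make room for a null allele."""
    if null_rate == 0:
        return list(freqs)
    return [
        LocusFrequencies(lf.locus, lf.alleles, lf.freqs * (1 - null_rate), null_rate)
        for lf in freqs
    ]


def _draw_true_genotypes(
    rng: np.random.Generator, lf: LocusFrequencies, n: int
) -> np.ndarray:
    """(n, 2) true allele labels (NULL possible) under HWE."""
    labels = np.concatenate([lf.alleles, [NULL]]) if lf.null_freq > 0 else lf.alleles
    probs = (
        np.concatenate([lf.freqs, [lf.null_freq]]) if lf.null_freq > 0 else lf.freqs
    )
    probs = probs / probs.sum()
    return rng.choice(labels, size=(n, 2), p=probs)


def _apparent(genotypes: np.ndarray) -> np.ndarray:
    """Map true genotypes to scored genotypes under the null-allele model."""
    g = np.array(genotypes, dtype=np.int64)
    single = np.sum(g == NULL, axis=-1) == 1
    if single.any():
        visible = np.where(g[single] == NULL, g[single][:, ::-1], g[single])
        g[single] = visible
    double = np.all(g == NULL, axis=-1)
    g[double] = MISSING
    return np.sort(g, axis=-1)


def _mendelian_child(
    rng: np.random.Generator, p1: np.ndarray, p2: np.ndarray
) -> np.ndarray:
    """One offspring per row: one uniformly chosen allele from each parent."""
    n = p1.shape[0]
    a = p1[np.arange(n), rng.integers(0, 2, n)]
    b = p2[np.arange(n), rng.integers(0, 2, n)]
    return np.stack([a, b], axis=-1)


# -- population simulation --------------------------------------------------


def simulate_population(
    config: SimulationConfig,
    freqs: Sequence[LocusFrequencies] | None = None,
) -> tuple[GenotypeMatrix, SampleMetadata, TruthTables]:
    """Simulate genotypes, metadata and ground truth for one population.

    Founders are HWE draws at the true frequencies (visible alleles rescaled
    by the null rate); offspring inherit one uniformly chosen allele from
    each parent. Family members are placed at a uniform family anchor plus
    isotropic Gaussian noise of scale ``kin_sigma_km``; unrelated individuals
    uniform over the arena. Duplicates copy an individual's true genotype,
    coordinates and measurements, then receive independent missingness.
    Passing ``freqs`` (null-free visible frequencies) overrides the internal
    Dirichlet draw while keeping the rest of the configuration.
    """
    rng = np.random.default_rng(config.seed)
    if freqs is None:
        visible = generate_allele_frequencies(
            config.n_loci,
            config.alleles_per_locus,
            config.freq_concentration,
            rng,
            config.motif_step,
        )
    else:
        if len(freqs) != config.n_loci:
            raise ValueError("freqs length must equal n_loci")
        visible = [
            LocusFrequencies(lf.locus, lf.alleles, lf.freqs / lf.freqs.sum(), 0.0)
            for lf in freqs
        ]
    true_freqs = _with_null(visible, config.null_rate_per_locus)
    L = config.n_loci

    ids: list[str] = []
    true_geno: list[np.ndarray] = []  # per individual: (L, 2) true alleles
    family_label: dict[str, str | None] = {}
    dyads: dict[tuple[str, str], str] = {}
    anchors: list[tuple[str | None, int]] = []  # (family id or None, index)

    def hwe_individual() -> np.ndarray:
        return np.stack([_draw_true_genotypes(rng, lf, 1)[0] for lf in true_freqs])

    def record_dyad(a: str, b: str, rel: str) -> None:
        dyads[tuple(sorted((a, b)))] = rel

    fam_counter = 0
    for rel, size, count in config.family_spec:
        for _ in range(count):
            fam_counter += 1
            fam = f"F{fam_counter:03d}"
            members: list[str] = []
            if rel == "FS":
                p1, p2 = hwe_individual(), hwe_individual()
                for m in range(size):
                    members.append(f"{fam}_{m + 1}")
                    true_geno.append(_mendelian_child(rng, p1, p2))
                for a in range(size):
                    for b in range(a + 1, size):
                        record_dyad(members[a], members[b], "FS")
            elif rel == "HS":
                shared = hwe_individual()
                for m in range(size):
                    members.append(f"{fam}_{m + 1}")
                    true_geno.append(_mendelian_child(rng, shared, hwe_individual()))
                for a in range(size):
                    for b in range(a + 1, size):
                        record_dyad(members[a], members[b], "HS")
            else:  # PO: sampled parent + offspring by distinct latent mates
                parent = hwe_individual()
                members.append(f"{fam}_1")
                true_geno.append(parent)
                for m in range(1, size):
                    members.append(f"{fam}_{m + 1}")
                    true_geno.append(_mendelian_child(rng, parent, hwe_individual()))
                for m in range(1, size):
                    record_dyad(members[0], members[m], "PO")
                for a in range(1, size):
                    for b in range(a + 1, size):
                        record_dyad(members[a], members[b], "HS")
            for m, ident in enumerate(members):
                ids.append(ident)
                family_label[ident] = fam
                anchors.append((fam, len(ids) - 1))

    for u in range(config.n_unrelated):
        ident = f"U{u + 1:03d}"
        ids.append(ident)
        true_geno.append(hwe_individual())
        family_label[ident] = None
        anchors.append((None, len(ids) - 1))

    # -- coordinates and measurements
    lat0, lat1, lon0, lon1 = config.arena
    mid_lat = 0.5 * (lat0 + lat1)
    fam_ids = sorted({f for f, _ in anchors if f is not None})
    fam_anchor = {
        f: (rng.uniform(lat0, lat1), rng.uniform(lon0, lon1)) for f in fam_ids
    }
    lats = np.empty(len(ids))
    lons = np.empty(len(ids))
    for fam, idx in anchors:
        if fam is None:
            lats[idx] = rng.uniform(lat0, lat1)
            lons[idx] = rng.uniform(lon0, lon1)
        else:
            alat, alon = fam_anchor[fam]
            dkm = rng.normal(0.0, config.kin_sigma_km, size=2)
            lats[idx] = alat + dkm[0] / KM_PER_DEG
            lons[idx] = alon + dkm[1] / (KM_PER_DEG * np.cos(np.radians(mid_lat)))
    depth = np.clip(rng.normal(4.9, 7.4, len(ids)), 0.0, 26.0)
    width = np.clip(23.2 + 0.12 * depth + rng.normal(0.0, 3.0, len(ids)), 5.0, None)

    # -- duplicates: copy of an existing individual, independent missingness
    sources = rng.choice(len(ids), size=config.n_duplicates, replace=False)
    dup_entries: list[tuple[str, int]] = []
    for src in sources:
        src = int(src)
        dup_id = f"{ids[src]}_dup"
        dup_entries.append((dup_id, src))
        record_dyad(ids[src], dup_id, "DUP")
        # the copy inherits every kinship tie of its source
        for (a, b), rel in list(dyads.items()):
            if rel == "DUP":
                continue
            other = b if a == ids[src] else a if b == ids[src] else None
            if other is not None:
                record_dyad(dup_id, other, rel)
        family_label[dup_id] = family_label[ids[src]]

    all_ids = ids + [d for d, _ in dup_entries]
    n_total = len(all_ids)
    true_arr = np.stack(true_geno + [true_geno[src] for _, src in dup_entries])
    apparent = _apparent(true_arr)

    if config.missing_rate > 0:
        mask = rng.random((n_total, L)) < config.missing_rate
        apparent[mask] = MISSING

    lats = np.concatenate([lats, lats[[s for _, s in dup_entries]]])
    lons = np.concatenate([lons, lons[[s for _, s in dup_entries]]])
    depth = np.concatenate([depth, depth[[s for _, s in dup_entries]]])
    width = np.concatenate([width, width[[s for _, s in dup_entries]]])

    gm = GenotypeMatrix(all_ids, [lf.locus for lf in true_freqs], apparent)
    meta = SampleMetadata(
        pd.DataFrame(
            {"lat": lats, "lon": lons, "depth_m": depth, "width_cm": width},
            index=pd.Index(all_ids, name="id"),
        )
    )
    truth = TruthTables(
        dyad_relationship=dyads,
        family_label=family_label,
        true_null_freq={lf.locus: lf.null_freq for lf in true_freqs},
        true_allele_freqs={lf.locus: lf for lf in true_freqs},
    )
    return gm, meta, truth


# -- dyad calibration harness ----------------------------------------------


def simulate_dyads(
    relationship: str,
    n_dyads: int,
    freqs: Sequence[LocusFrequencies],
    seed: int | np.random.Generator,
) -> tuple[np.ndarray, np.ndarray]:
    """Simulate genotype pairs under the exact IBD-mode mixture of a class.

    Returns two (n_dyads, n_loci, 2) apparent-genotype arrays. Per dyad and
    locus the IBD mode is drawn from the class's (k0, k1, k2); loci are
    independent. Frequencies may carry a null allele, in which case the
    null-visibility mapping is applied before returning.
    """
    if relationship not in K_COEFFICIENTS:
        raise ValueError(
            f"unknown relationship {relationship!r}; expected one of "
            f"{sorted(K_COEFFICIENTS)}"
        )
    if n_dyads < 1:
        raise ValueError("n_dyads must be >= 1")
    rng = np.random.default_rng(seed) if not isinstance(seed, np.random.Generator) else seed
    k = np.asarray(K_COEFFICIENTS[relationship])
    L = len(freqs)
    g1 = np.empty((n_dyads, L, 2), dtype=np.int64)
    g2 = np.empty((n_dyads, L, 2), dtype=np.int64)
    for j, lf in enumerate(freqs):
        a1 = _draw_true_genotypes(rng, lf, n_dyads)
        fresh = _draw_true_genotypes(rng, lf, n_dyads)
        modes = rng.choice(3, size=n_dyads, p=k)
        pick = rng.integers(0, 2, n_dyads)
        b = fresh.copy()
        one = modes == 1
        # share one uniformly chosen allele of genotype 1; the partner's
        # other allele stays a fresh population draw
        b[one, 0] = a1[one, pick[one]]
        two = modes == 2
        b[two] = a1[two]
        g1[:, j, :] = a1
        g2[:, j, :] = b
    return _apparent(g1), _apparent(g2)
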