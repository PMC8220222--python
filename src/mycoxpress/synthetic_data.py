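"""Ground-truth generators for every input class of the pipeline.

Field data for this kind of study (hundreds of millions of reads, external
homology databases) cannot be re-derived at desk scale, so each stage is
exercised on synthetic cohorts whose truth is known by construction:

* contig cohorts with taxonomy/orthology/expression evidence matching their
  plant-or-contaminant label under the decontamination rules;
* negative-binomially distributed counts for a 4-species × 2-organ × paired-
  individuals design with planted underground/stem ratio inversions;
* pathway/ortholog detection tables with planted group-specific losses.

Every generator is a pure function of its spec and seed.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .decontam import ContigEvidence
from .io_formats import CountMatrix, HitRecord, OrthogroupMap
from .repertoire import DetectionMatrix

PLANT_LINEAGE = ("Eukaryota", "Viridiplantae", "Streptophyta", "Orchidaceae")
FUNGAL_LINEAGE = ("Eukaryota", "Fungi", "Basidiomycota", "Agaricomycetes")
BACTERIAL_LINEAGE = ("Bacteria", "Proteobacteria")

#: default 6-sample design of one species: 2 individuals × 3 tissues
DEFAULT_TISSUES = ("flower", "flower", "stem", "stem", "underground", "underground")

# default distributions over the number of expressing samples (0–6) per
# evidence class; contaminants are weighted toward the underground samples
# separately (see gen_contig_cohort)
DEFAULT_DETECTION_PROFILE = {
    "plant": (0.00, 0.02, 0.08, 0.15, 0.25, 0.25, 0.25),
    "contaminant": (0.05, 0.35, 0.40, 0.15, 0.05, 0.00, 0.00),
    "nohit": (0.25, 0.25, 0.20, 0.15, 0.10, 0.05, 0.00),
}


@dataclass
class ContigCohortSpec:
    n_plant: int = 100
    n_contaminant: int = 50
    n_nohit: int = 50
    p_orthogroup_rescue: float = 0.0
    detection_profile: Mapping[str, Sequence[float]] = field(
        default_factory=lambda: dict(DEFAULT_DETECTION_PROFILE))
    tissues: Sequence[str] = DEFAULT_TISSUES
    min_detect: int = 2
    seed: int = 0

    def __post_init__(self):
        if min(self.n_plant, self.n_contaminant, self.n_nohit) < 0:
            raise ValueError("counts must be non-negative")
        if not (0.0 <= self.p_orthogroup_rescue <= 1.0):
            raise ValueError("p_orthogroup_rescue must be in [0, 1]")
        for cls, probs in self.detection_profile.items():
            probs = np.asarray(probs, dtype=float)
            if len(probs) != len(self.tissues) + 1 or not np.isclose(probs.sum(), 1.0):
                raise ValueError(f"detection profile for {cls!r} is not a "
                                 f"distribution over 0..{len(self.tissues)}")


@dataclass
class ContigCohort:
    evidence: list[ContigEvidence]
    truth: pd.Series          # contig id → "plant" | "contaminant"
    tissue_of_sample: tuple[str, ...]


def _draw_detection(rng: np.random.Generator, probs: Sequence[float],
                    n_samples: int, weights: np.ndarray) -> tuple[bool, ...]:
    k = int(rng.choice(len(probs), p=np.asarray(probs, dtype=float)))
    vec = np.zeros(n_samples, dtype=bool)
    if k > 0:
        idx = rng.choice(n_samples, size=k, replace=False,
                         p=weights / weights.sum())
        vec[idx] = True
    return tuple(bool(v) for v in vec)


def gen_contig_cohort(spec: ContigCohortSpec) -> ContigCohort:
    """Generate contig evidence with labels consistent with the filter rules.

    Plant contigs carry a best hit inside Streptophyta. Contaminant-class
    contigs carry a fungal or bacterial best hit, detected mostly in the
    underground samples (as the mycorrhizal fungus is); with probability
    ``p_orthogroup_rescue`` such a contig is instead a deeply conserved
    plant gene — it shares a reference orthogroup and its truth label is
    plant. No-hit contigs are genuine plant transcripts when expressed in
    at least ``min_detect`` samples, assembly noise otherwise.
    """
    rng = np.random.default_rng(spec.seed)
    n_samples = len(spec.tissues)
    uniform = np.ones(n_samples)
    underground_biased = np.where(
        np.asarray(spec.tissues) == "underground", 8.0, 1.0)

    evidence: list[ContigEvidence] = []
    truth: dict[str, str] = {}

    for i in range(spec.n_plant):
        cid = f"plant_{i:06d}"
        det = _draw_detection(rng, spec.detection_profile["plant"],
                              n_samples, uniform)
        hit = HitRecord(cid, f"sp|P{i:06d}", float(rng.uniform(80, 500)),
                        float(10.0 ** rng.uniform(-80, -5)), PLANT_LINEAGE)
        og = f"OG{rng.integers(0, 10 ** 7):07d}"
        evidence.append(ContigEvidence(cid, hit, og, False, det))
        truth[cid] = "plant"

    for i in range(spec.n_contaminant):
        cid = f"cont_{i:06d}"
        det = _draw_detection(rng, spec.detection_profile["contaminant"],
                              n_samples, underground_biased)
        lineage = FUNGAL_LINEAGE if rng.random() < 0.9 else BACTERIAL_LINEAGE
        hit = HitRecord(cid, f"sp|C{i:06d}", float(rng.uniform(80, 500)),
                        float(10.0 ** rng.uniform(-80, -5)), lineage)
        rescued = bool(rng.random() < spec.p_orthogroup_rescue)
        og = f"OGREF{rng.integers(0, 10 ** 6):06d}" if rescued else None
        evidence.append(ContigEvidence(cid, hit, og, rescued, det))
        truth[cid] = "plant" if rescued else "contaminant"

    for i in range(spec.n_nohit):
        cid = f"nohit_{i:06d}"
        det = _draw_detection(rng, spec.detection_profile["nohit"],
                              n_samples, uniform)
        evidence.append(ContigEvidence(cid, None, None, False, det))
        truth[cid] = "plant" if sum(det) >= spec.min_detect else "contaminant"

    return ContigCohort(evidence, pd.Series(truth, name="truth"),
                        tuple(spec.tissues))


# ---------------------------------------------------------------------------
# counts for the cross-species ratio design


@dataclass
class CountSimSpec:
    n_orthogroups: int = 1000
    #: species id → trophic mode; defaults mirror the study design of two
    #: mycoheterotrophic orchids vs two autotrophic grasses
    species: Mapping[str, str] = field(default_factory=lambda: {
        "NNA": "MH", "EA": "MH", "ZM": "AT", "BD": "AT"})
    individuals_per_species: int = 2
    nb_mean_range: tuple[float, float] = (5.0, 500.0)
    nb_dispersion: float = 0.1
    frac_inverted: float = 0.0
    inversion_effect: float = 1.5
    frac_species_missing: float = 0.0
    #: spread (log2 scale) of the shared underground/stem baseline ratio
    baseline_ratio_sd: float = 1.0
    max_genes_per_orthogroup: int = 3
    library_factor_range: tuple[float, float] = (0.5, 2.0)
    seed: int = 0

    def __post_init__(self):
        if self.frac_inverted + self.frac_species_missing > 1.0:
            raise ValueError("frac_inverted + frac_species_missing must be ≤ 1")
        if self.nb_dispersion <= 0:
            raise ValueError("dispersion must be positive")
        trophic = set(self.species.values())
        if not trophic <= {"MH", "AT"}:
            raise ValueError(f"trophic labels must be MH/AT, got {trophic}")


@dataclass
class CountExperiment:
    counts: CountMatrix          # all species' genes × all samples
    orthogroups: OrthogroupMap
    truth_inverted: set[str]
    truth_null: set[str]
    truth_missing: set[str]      # orthogroups silenced in one species


def _nb_draw(rng: np.random.Generator, mean: np.ndarray, phi: float) -> np.ndarray:
    """NB(mean μ, dispersion φ), Var = μ + φμ², via the gamma–Poisson mixture."""
    shape = 1.0 / phi
    lam = rng.gamma(shape, mean * phi)
    return rng.poisson(lam)


def gen_count_experiment(spec: CountSimSpec) -> CountExperiment:
    """Simulate paired underground/stem counts with planted ratio inversions.

    Every orthogroup has a baseline log2 underground/stem ratio shared by
    all species (null orthogroups). Inverted orthogroups instead get ratio
    ±effect in MH species and ∓effect in AT species (orientation random per
    orthogroup, so inversions go both ways, as in real reprogramming), i.e.
    opposite-signed true group means. A ``frac_species_missing`` fraction of
    orthogroups is silenced in one
    random species to exercise the all-species detection filter. Counts are
    NB at the gene level with library factors log-uniform in
    ``library_factor_range`` so TMM is non-trivial.
    """
    rng = np.random.default_rng(spec.seed)
    G = spec.n_orthogroups
    species = list(spec.species)
    og_ids = [f"OG{i:06d}" for i in range(G)]

    n_inv = int(round(spec.frac_inverted * G))
    n_miss = int(round(spec.frac_species_missing * G))
    perm = rng.permutation(G)
    inverted = set(np.array(og_ids)[perm[:n_inv]])
    missing = set(np.array(og_ids)[perm[n_inv:n_inv + n_miss]])
    null = set(og_ids) - inverted - missing
    missing_species = {og: species[int(rng.integers(len(species)))]
                       for og in missing}

    base = np.exp(rng.uniform(np.log(spec.nb_mean_range[0]),
                              np.log(spec.nb_mean_range[1]), size=G))
    baseline_ratio = rng.normal(0.0, spec.baseline_ratio_sd, size=G)
    orientation = rng.choice([-1.0, 1.0], size=G)  # inversion direction per og
    species_scale = {sp: float(np.exp(rng.uniform(np.log(0.5), np.log(2.0))))
                     for sp in species}

    # sample metadata
    meta_rows = []
    for sp in species:
        for ind in range(1, spec.individuals_per_species + 1):
            for organ in ("underground", "stem"):
                sid = f"{sp}_{organ}_{ind}"
                meta_rows.append((sid, sp, organ, f"ind{ind}", spec.species[sp]))
    meta = (pd.DataFrame(meta_rows, columns=["sample_id", "species", "organ",
                                             "individual", "trophic"])
            .set_index("sample_id"))
    lib_factor = {sid: float(np.exp(rng.uniform(
        np.log(spec.library_factor_range[0]),
        np.log(spec.library_factor_range[1])))) for sid in meta.index}

    # gene structure: 1..max genes per orthogroup per species
    members: dict[str, dict[str, list[str]]] = {og: {} for og in og_ids}
    gene_rows: list[str] = []
    gene_og: list[int] = []
    gene_sp: list[str] = []
    gene_prop: list[float] = []
    for gi, og in enumerate(og_ids):
        for sp in species:
            k = int(rng.integers(1, spec.max_genes_per_orthogroup + 1))
            props = rng.dirichlet(np.ones(k))
            names = [f"{sp}_g{gi:06d}_{j}" for j in range(k)]
            members[og][sp] = names
            gene_rows.extend(names)
            gene_og.extend([gi] * k)
            gene_sp.extend([sp] * k)
            gene_prop.extend(props.tolist())
    omap = OrthogroupMap(species=tuple(species), members=members)

    gene_og = np.asarray(gene_og)
    gene_prop = np.asarray(gene_prop)
    gene_sp = np.asarray(gene_sp)

    counts = pd.DataFrame(0, index=gene_rows, columns=list(meta.index),
                          dtype="int64")
    ratio = np.empty((G, len(species)))
    inv_mask = np.array([og in inverted for og in og_ids])
    for si, sp in enumerate(species):
        r = baseline_ratio.copy()
        sign = 1.0 if spec.species[sp] == "MH" else -1.0
        r[inv_mask] = sign * orientation[inv_mask] * spec.inversion_effect
        ratio[:, si] = r

    silenced = np.zeros((G, len(species)), dtype=bool)
    for og, sp in missing_species.items():
        silenced[og_ids.index(og), species.index(sp)] = True

    for si, sp in enumerate(species):
        sel = gene_sp == sp
        og_idx = gene_og[sel]
        props = gene_prop[sel]
        genes = np.asarray(gene_rows)[sel]
        sp_base = base[og_idx] * species_scale[sp] * props
        for sid in meta.index[meta["species"] == sp]:
            organ = meta.loc[sid, "organ"]
            shift = 0.5 if organ == "underground" else -0.5
            mu = sp_base * 2.0 ** (shift * ratio[og_idx, si]) * lib_factor[sid]
            mu = np.where(silenced[og_idx, si], 0.0, mu)
            draw = np.zeros(len(mu), dtype="int64")
            pos = mu > 0
            draw[pos] = _nb_draw(rng, mu[pos], spec.nb_dispersion)
            counts.loc[genes, sid] = draw

    cm = CountMatrix(counts, meta)
    return CountExperiment(cm, omap, inverted, null, missing)


# ---------------------------------------------------------------------------
# single-species organ design (for the within-species DE analysis)


def gen_organ_counts(n_genes: int = 2000, n_individuals: int = 2,
                     organs: Sequence[str] = ("flower", "stem", "underground"),
                     mean_range: tuple[float, float] = (5.0, 500.0),
                     dispersion: float = 0.1, frac_de: float = 0.0,
                     log2_effect: float = 2.0,
                     library_factor_range: tuple[float, float] = (0.5, 2.0),
                     contrast: tuple[str, str] = ("underground", "stem"),
                     species: str = "NNA", trophic: str = "MH",
                     seed: int = 0) -> tuple[pd.DataFrame, pd.DataFrame, set[str]]:
    """One species' organ × individual NB counts with optional planted effects.

    A ``frac_de`` fraction of genes gets a ``log2_effect`` shift (random
    sign) between the two contrast organs; all other genes share one mean
    across organs, so the null holds exactly for them. Returns (counts,
    metadata, true-DE gene ids).
    """
    rng = np.random.default_rng(seed)
    genes = [f"g{i:06d}" for i in range(n_genes)]
    n_de = int(round(frac_de * n_genes))
    de_idx = rng.permutation(n_genes)[:n_de]
    de_set = {genes[i] for i in de_idx}
    sign = np.zeros(n_genes)
    sign[de_idx] = rng.choice([-1.0, 1.0], size=n_de)

    base = np.exp(rng.uniform(np.log(mean_range[0]), np.log(mean_range[1]),
                              size=n_genes))
    rows = []
    for ind in range(1, n_individuals + 1):
        for organ in organs:
            rows.append((f"{species}_{organ}_{ind}", species, organ,
                         f"ind{ind}", trophic))
    meta = (pd.DataFrame(rows, columns=["sample_id", "species", "organ",
                                        "individual", "trophic"])
            .set_index("sample_id"))

    counts = {}
    for sid in meta.index:
        organ = meta.loc[sid, "organ"]
        if organ == contrast[0]:
            shift = 0.5
        elif organ == contrast[1]:
            shift = -0.5
        else:
            shift = 0.0
        lib = np.exp(rng.uniform(np.log(library_factor_range[0]),
                                 np.log(library_factor_range[1])))
        mu = base * 2.0 ** (shift * sign * log2_effect) * lib
        counts[sid] = _nb_draw(rng, mu, dispersion)
    df = pd.DataFrame(counts, index=genes).astype("int64")
    return df, meta, de_set


# ---------------------------------------------------------------------------
# pathway repertoires with planted losses


@dataclass
class RepertoireTruth:
    detection: DetectionMatrix
    pathway_map: dict[str, list[str]]
    lost_pathways: set[str]


def gen_repertoire(n_pathways: int = 100, orthologs_per_pathway: int = 40,
                   lost_pathways: int = 0, loss_fraction: float = 0.0,
                   groups: Mapping[str, Sequence[str]] | None = None,
                   lost_in: str = "MH", p_detect: float = 0.9,
                   seed: int = 0) -> RepertoireTruth:
    """Simulate per-species ortholog detection with group-specific losses.

    Every species detects each ortholog with probability ``p_detect``;
    in the ``lost_pathways`` first pathways, species of the ``lost_in``
    group detect with probability ``p_detect · (1 − loss_fraction)``
    instead. ``loss_fraction = 0`` is the global null.
    """
    if not (0.0 <= loss_fraction <= 1.0):
        raise ValueError("loss_fraction must be in [0, 1]")
    if groups is None:
        groups = {"AT": ["AS", "DC", "PE"], "MH": ["GE", "EA", "NNA"]}
    if lost_in not in groups:
        raise ValueError(f"unknown focal group {lost_in!r}")
    rng = np.random.default_rng(seed)
    species = [sp for grp in groups.values() for sp in grp]
    focal = set(groups[lost_in])

    pathway_map: dict[str, list[str]] = {}
    lost: set[str] = set()
    all_orthologs: list[str] = []
    det_rows = []
    for pi in range(n_pathways):
        pid = f"pw{pi:04d}"
        orthologs = [f"{pid}_ko{j:03d}" for j in range(orthologs_per_pathway)]
        pathway_map[pid] = orthologs
        all_orthologs.extend(orthologs)
        is_lost = pi < lost_pathways and loss_fraction > 0
        if is_lost:
            lost.add(pid)
        for _ in orthologs:
            row = []
            for sp in species:
                p = p_detect * (1.0 - loss_fraction) \
                    if (is_lost and sp in focal) else p_detect
                row.append(rng.random() < p)
            det_rows.append(row)
    detected = pd.DataFrame(det_rows, index=all_orthologs, columns=species)
    return RepertoireTruth(DetectionMatrix(detected), pathway_map, lost)
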