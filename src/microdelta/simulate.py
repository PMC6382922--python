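"""Synthetic paired two-arm cohort generator with ground-truth records.

Emulates the statistical structure of a three-year, two-arm (UDCA vs
placebo) chemoprevention trial with paired stool samples: 198/203 subjects
per arm sampled at baseline and end-of-study (802 samples), variable
sequencing depth with a small tail below the 900-read rarefaction depth,
subject-level intraclass correlation around 0.5, a small treatment-consistent
compositional shift in designated taxa, block-structured taxon correlations
with two designated hub species (a *Faecalibacterium prausnitzii*-like hub
positively coupled to its block and negatively to a *Ruminococcus
gnavus*-like species, active only in post-treatment samples of the treated
arm), and binary adenoma outcomes coupled — in males only — to each
subject's change in the two hub species.

The generative model
--------------------
Per sample *s* and feature *f* the latent log-abundance is

    L[s, f] = mu[f] + a[subject(s), f] + shift[f] * 1{UDCA, end} + e[s, f]

with feature baselines ``mu ~ N(0, 1.5^2)``, subject random effects
``a ~ N(0, sigma_b^2)`` and within-subject noise ``e`` of unit variance,
``sigma_b^2 = icc/(1-icc)`` so the between/within variance ratio hits the
ICC target.  Within a correlation block the noise ``e`` shares a common
factor (loading ``±sqrt(rho)``), which induces correlated *basis*
abundances.  Counts are multinomial draws at the sample's depth from
``softmax(L[s, :])`` — the compositional closure that produces the spurious
negative correlations SparCC is designed to undo.  Depths are log-normal.
"""

from __future__ import annotations

import math
import random as _pyrandom
from dataclasses import dataclass, field

import dendropy
import numpy as np
import pandas as pd
from skbio import TreeNode

from .core_io import CohortMetadata, FeatureTable, TaxonomyMap

__all__ = [
    "CorrelationBlock",
    "HubSpec",
    "OutcomeModel",
    "SimulationConfig",
    "SimulationTruth",
    "simulate_cohort",
    "write_cohort",
]


@dataclass(frozen=True)
class CorrelationBlock:
    """A set of features sharing a latent factor with loading sqrt(rho).

    ``anti`` lists members loaded with the opposite sign (pairwise basis
    correlation ``-rho`` against the rest of the block).  ``condition``
    restricts the factor to a subset of samples: ``'all'``, ``'udca_end'``
    or ``'placebo_end'``.  If ``hub`` names a member, that member's own
    noise *is* the shared factor — a keystone-species structure in which
    the hub correlates with every member at ``±sqrt(rho)`` while members
    correlate with each other only at ``±rho``, making the hub the
    strongest node of the block.
    """

    features: tuple[int, ...]
    rho: float
    condition: str = "all"
    anti: tuple[int, ...] = ()
    hub: int | None = None

    def __post_init__(self):
        if not (0 <= self.rho < 1):
            raise ValueError("|rho| must be in [0, 1)")
        if self.condition not in ("all", "udca_end", "placebo_end"):
            raise ValueError(f"unknown condition {self.condition!r}")
        if set(self.anti) - set(self.features):
            raise ValueError("anti members must be block members")
        if self.hub is not None and self.hub not in self.features:
            raise ValueError("hub must be a block member")
        if self.hub is not None and self.hub in self.anti:
            raise ValueError("hub cannot be anti-loaded against itself")


@dataclass(frozen=True)
class HubSpec:
    """Indices and species labels of the two designated hub taxa."""

    hub_positive: int   # F. prausnitzii-like: positive within-block coupling
    hub_negative: int   # R. gnavus-like: negatively coupled to the hub block
    species_positive: str = "Faecalibacterium prausnitzii"
    species_negative: str = "Ruminococcus gnavus"


@dataclass(frozen=True)
class OutcomeModel:
    """Male-only logistic coupling of adenoma outcome to hub-taxon change.

    ``P(outcome) = expit(intercept + beta_negative_hub * dL_gnavus +
    beta_positive_hub * dL_prausnitzii)`` where ``dL`` is the subject's
    end-minus-baseline latent log-abundance of the hub feature.  Females are
    intercept-only.  Defaults give a ~45% marginal event rate with an
    increase in the *R. gnavus*-like species raising risk and an increase in
    the *F. prausnitzii*-like species lowering it.
    """

    intercept: float = -0.2
    beta_negative_hub: float = 1.2    # R. gnavus-like: increase -> higher risk
    beta_positive_hub: float = -1.2   # F. prausnitzii-like: increase -> lower risk
    advanced_fraction: float = 0.3    # advanced | any


def _default_blocks(n_features: int) -> tuple[CorrelationBlock, ...]:
    """Hub block (treated-arm-only) plus one unconditional background block."""
    if n_features < 30:
        raise ValueError("default blocks need at least 30 features")
    # within-subject noise correlations are diluted by the independent
    # subject effects (factor 1/(1+sigma_b^2)), so the block rho is set high
    # enough that the *realized* taxon correlations land near 0.3-0.4 — the
    # strength of the hub edges the analysis is meant to detect
    hub_block = CorrelationBlock(
        features=tuple(range(0, 6)) + (6,), rho=0.8, condition="udca_end",
        anti=(6,), hub=0,
    )
    background = CorrelationBlock(
        features=tuple(range(10, 16)), rho=0.5, condition="all"
    )
    return (hub_block, background)


@dataclass(frozen=True)
class SimulationConfig:
    """All knobs of the cohort generator, fully reproducible from ``seed``."""

    n_udca: int = 198
    n_placebo: int = 203
    n_features: int = 150
    seed: int = 0
    icc_target: float = 0.55
    arm_shift_magnitude: float = 0.8
    # the gradient loading is deliberately weak per feature: axis dominance
    # in ordination scales with n_loaded * loading^2 while the pairwise
    # correlation it induces scales with loading^2 only, so a weak loading
    # spread over the many Firmicutes/Bacteroidetes features makes PC1 the
    # community gradient without planting network-visible edges
    gradient_shift: float = 0.25
    gradient_loading: float = 0.0
    correlation_blocks: tuple[CorrelationBlock, ...] | None = None
    hub_spec: HubSpec = field(default_factory=lambda: HubSpec(0, 6))
    outcome_model: OutcomeModel = field(default_factory=OutcomeModel)
    depth_log_mean: float = math.log(4500.0)
    depth_log_sigma: float = 0.8
    min_depth: int = 100
    baseline_sigma: float = 1.5
    male_fraction_udca: float = 150 / 198
    male_fraction_placebo: float = 133 / 203
    aspirin_fraction_udca: float = 64 / 198
    aspirin_fraction_placebo: float = 39 / 203
    batch_mismatch_fraction: float = 0.1
    storage_mean_baseline: float = 17.2
    storage_mean_end: float = 14.6
    storage_sd: float = 1.1

    def __post_init__(self):
        if not (0 < self.icc_target < 0.95):
            raise ValueError(
                "icc_target must lie in (0, 0.95): unit within-subject noise "
                "puts higher values out of reach"
            )
        if self.correlation_blocks is not None:
            used: set[int] = set()
            for b in self.correlation_blocks:
                if used & set(b.features) and b.condition == "all":
                    raise ValueError("unconditional block index sets must be disjoint")
                used |= set(b.features)
                if max(b.features) >= self.n_features:
                    raise ValueError("block feature index out of range")

    def blocks(self) -> tuple[CorrelationBlock, ...]:
        if self.correlation_blocks is not None:
            return self.correlation_blocks
        return _default_blocks(self.n_features)


@dataclass(frozen=True)
class SimulationTruth:
    """Ground truth for parameter-recovery tests."""

    latent: pd.DataFrame              # samples x features latent log-abundance
    subject_effects: pd.DataFrame     # subjects x features random effects
    basis_correlation: dict[str, np.ndarray]  # condition -> features x features
    shift: np.ndarray                 # per-feature UDCA end-of-study shift
    outcome_model: OutcomeModel
    hub_features: tuple[str, str]     # (positive hub id, negative hub id)
    icc_target: float

    def __post_init__(self):
        for c, m in self.basis_correlation.items():
            if not np.allclose(m, m.T):
                raise ValueError(f"basis correlation for {c!r} not symmetric")
            w = np.linalg.eigvalsh(m)
            if w.min() < -1e-8:
                raise ValueError(f"basis correlation for {c!r} not PSD")


# -- taxonomy -----------------------------------------------------------

_GENUS_PHYLUM = {
    "Faecalibacterium": ("Firmicutes", "Clostridia", "Clostridiales", "Ruminococcaceae"),
    "Ruminococcus": ("Firmicutes", "Clostridia", "Clostridiales", "Lachnospiraceae"),
    "Blautia": ("Firmicutes", "Clostridia", "Clostridiales", "Lachnospiraceae"),
    "Roseburia": ("Firmicutes", "Clostridia", "Clostridiales", "Lachnospiraceae"),
    "Dorea": ("Firmicutes", "Clostridia", "Clostridiales", "Lachnospiraceae"),
    "Coprococcus": ("Firmicutes", "Clostridia", "Clostridiales", "Lachnospiraceae"),
    "Oscillospira": ("Firmicutes", "Clostridia", "Clostridiales", "Ruminococcaceae"),
    "Clostridium": ("Firmicutes", "Clostridia", "Clostridiales", "Clostridiaceae"),
    "Streptococcus": ("Firmicutes", "Bacilli", "Lactobacillales", "Streptococcaceae"),
    "Lactobacillus": ("Firmicutes", "Bacilli", "Lactobacillales", "Lactobacillaceae"),
    "Bacteroides": ("Bacteroidetes", "Bacteroidia", "Bacteroidales", "Bacteroidaceae"),
    "Prevotella": ("Bacteroidetes", "Bacteroidia", "Bacteroidales", "Prevotellaceae"),
    "Parabacteroides": ("Bacteroidetes", "Bacteroidia", "Bacteroidales", "Porphyromonadaceae"),
    "Escherichia": ("Proteobacteria", "Gammaproteobacteria", "Enterobacteriales", "Enterobacteriaceae"),
    "Bilophila": ("Proteobacteria", "Deltaproteobacteria", "Desulfovibrionales", "Desulfovibrionaceae"),
    "Fusobacterium": ("Fusobacteria", "Fusobacteriia", "Fusobacteriales", "Fusobacteriaceae"),
    "Bifidobacterium": ("Actinobacteria", "Actinobacteria", "Bifidobacteriales", "Bifidobacteriaceae"),
    "Akkermansia": ("Verrucomicrobia", "Verrucomicrobiae", "Verrucomicrobiales", "Verrucomicrobiaceae"),
}

#: Genera whose designated features receive the treatment shift (sign).
_SHIFT_GENERA_UP = ("Streptococcus", "Escherichia", "Bilophila")
_SHIFT_GENERA_DOWN = ("Fusobacterium",)


#: Relative frequency of ASV assignment per genus: gut communities are
#: dominated by Bacteroidetes and Clostridial Firmicutes.
_GENUS_WEIGHT = {
    "Bacteroides": 5.0, "Prevotella": 2.5, "Parabacteroides": 2.0,
    "Faecalibacterium": 2.5, "Ruminococcus": 2.0, "Blautia": 2.0,
    "Roseburia": 1.5, "Coprococcus": 1.5, "Oscillospira": 1.5, "Dorea": 1.0,
    "Clostridium": 1.0, "Lactobacillus": 0.5, "Streptococcus": 0.5,
    "Escherichia": 0.5, "Bilophila": 0.5, "Fusobacterium": 0.5,
    "Bifidobacterium": 1.0, "Akkermansia": 0.5,
}


def _make_taxonomy(
    feature_ids: list[str], cfg: SimulationConfig, rng: np.random.Generator
) -> TaxonomyMap:
    genera = list(_GENUS_PHYLUM)
    weights = np.array([_GENUS_WEIGHT[g] for g in genera])
    weights = weights / weights.sum()
    lineages: dict[str, tuple[str, ...]] = {}
    hub = cfg.hub_spec
    for i, fid in enumerate(feature_ids):
        if i == hub.hub_positive:
            genus, species = hub.species_positive.split(" ", 1)
        elif i == hub.hub_negative:
            genus, species = hub.species_negative.split(" ", 1)
        else:
            genus = genera[int(rng.choice(len(genera), p=weights))]
            species = ""
        phylum, clazz, order, family = _GENUS_PHYLUM[genus]
        # leave ~15% of ordinary features unresolved at genus level
        if species == "" and rng.random() < 0.15:
            genus = ""
        lineages[fid] = ("Bacteria", phylum, clazz, order, family, genus, species)
    return TaxonomyMap(lineages)


def _make_tree(
    feature_ids: list[str], seed: int, rng: np.random.Generator
) -> TreeNode:
    """Random rooted birth-death topology with exponential branch lengths."""
    t = dendropy.simulate.treesim.birth_death_tree(
        birth_rate=1.0,
        death_rate=0.2,
        num_extant_tips=len(feature_ids),
        rng=_pyrandom.Random(seed),
    )
    tips = list(t.leaf_node_iter())
    for tip, fid in zip(tips, feature_ids):
        tip.taxon.label = fid
    for edge in t.preorder_edge_iter():
        if edge.head_node is not t.seed_node:
            edge.length = float(rng.exponential(0.1))
    newick = t.as_string(schema="newick", suppress_rooting=True)
    import io as _io

    tree = TreeNode.read(_io.StringIO(newick))
    return tree


def _block_noise(
    n_samples: int,
    n_features: int,
    blocks: tuple[CorrelationBlock, ...],
    mask_for: dict[str, np.ndarray],
    rng: np.random.Generator,
) -> np.ndarray:
    """Unit-variance noise with block-factor correlation on masked samples."""
    e = rng.standard_normal((n_samples, n_features))
    for b in blocks:
        mask = mask_for[b.condition]
        if not mask.any() or b.rho == 0:
            continue
        if b.hub is not None:
            factor = e[mask, b.hub].copy()
        else:
            factor = rng.standard_normal(mask.sum())
        load = math.sqrt(b.rho)
        resid = math.sqrt(1.0 - b.rho)
        for f in b.features:
            if f == b.hub:
                continue
            sign = -1.0 if f in b.anti else 1.0
            e[mask, f] = sign * load * factor + resid * e[mask, f]
    return e


def _basis_correlation(
    n_features: int, blocks: tuple[CorrelationBlock, ...], condition: str
) -> np.ndarray:
    """Implied latent-noise correlation matrix under ``condition``."""
    c = np.eye(n_features)
    for b in blocks:
        if b.condition not in ("all", condition):
            continue
        root = math.sqrt(b.rho)
        for i in b.features:
            for j in b.features:
                if i == j:
                    continue
                si = -1.0 if i in b.anti else 1.0
                sj = -1.0 if j in b.anti else 1.0
                # hub-member pairs correlate at sqrt(rho), others at rho
                r = root if b.hub in (i, j) else b.rho
                c[i, j] = si * sj * r
    return c


def simulate_cohort(
    cfg: SimulationConfig,
) -> tuple[FeatureTable, TreeNode, TaxonomyMap, CohortMetadata, SimulationTruth]:
    """Draw one full paired cohort; identical output for identical config."""
    rng = np.random.default_rng(cfg.seed)
    n_subj = cfg.n_udca + cfg.n_placebo
    subjects = [f"S{i:04d}" for i in range(n_subj)]
    arms = np.array(["UDCA"] * cfg.n_udca + ["placebo"] * cfg.n_placebo)

    feature_ids = [f"ASV_{i:04d}" for i in range(cfg.n_features)]
    tax = _make_taxonomy(feature_ids, cfg, rng)
    tree = _make_tree(feature_ids, int(rng.integers(2**31 - 1)), rng)

    # subject-level covariates -----------------------------------------
    male_p = np.where(arms == "UDCA", cfg.male_fraction_udca, cfg.male_fraction_placebo)
    sex = np.where(rng.random(n_subj) < male_p, "M", "F")
    aspirin_p = np.where(
        arms == "UDCA", cfg.aspirin_fraction_udca, cfg.aspirin_fraction_placebo
    )
    aspirin = (rng.random(n_subj) < aspirin_p).astype(int)
    age = np.clip(rng.normal(66.3, 8.5, n_subj), 40, 90).round(1)
    batch = (rng.random(n_subj) < cfg.batch_mismatch_fraction).astype(int)
    storage_subject = rng.normal(0.0, 0.8, n_subj)

    # latent log-abundances --------------------------------------------
    sigma_b = math.sqrt(cfg.icc_target / (1.0 - cfg.icc_target))
    mu = rng.normal(0.0, cfg.baseline_sigma, cfg.n_features)
    # the designated hub species emulate abundant keystone taxa; a rare hub
    # would have its correlations swamped by count noise
    mu[cfg.hub_spec.hub_positive] = 1.5 * cfg.baseline_sigma
    mu[cfg.hub_spec.hub_negative] = 1.0 * cfg.baseline_sigma
    subject_eff = rng.normal(0.0, sigma_b, (n_subj, cfg.n_features))

    # community gradient: an optional subject-level Firmicutes(+)/
    # Bacteroidetes(-) axis.  With a nonzero loading the idiosyncratic
    # subject effect of loaded features is shrunk so their total
    # between-subject variance, hence per-feature ICC, is unchanged.  The
    # default loading is zero: a shared factor of any useful strength
    # plants dense taxon correlations that would contaminate the
    # co-occurrence networks, so the treatment's community-axis signal is
    # carried by the mean shift below instead.
    phylum_sign = np.array([
        1.0 if tax.lineage(fid)[1] == "Firmicutes"
        else -1.0 if tax.lineage(fid)[1] == "Bacteroidetes" else 0.0
        for fid in feature_ids
    ])
    if cfg.gradient_loading > 0:
        w = min(cfg.gradient_loading, 0.95 * sigma_b)
        lam = phylum_sign * w
        gradient = rng.normal(0.0, 1.0, n_subj)
        loaded = lam != 0
        shrink = math.sqrt(max(0.0, 1.0 - w**2 / sigma_b**2))
        subject_eff[:, loaded] = (shrink * subject_eff[:, loaded]
                                  + np.outer(gradient, lam[loaded]))

    sample_ids, subj_of, tp_of = [], [], []
    for i, s in enumerate(subjects):
        for tp, suffix in (("baseline", "B"), ("end", "E")):
            sample_ids.append(f"{s}.{suffix}")
            subj_of.append(i)
            tp_of.append(tp)
    subj_of = np.array(subj_of)
    tp_arr = np.array(tp_of)
    arm_arr = arms[subj_of]
    is_end = tp_arr == "end"
    n_samples = len(sample_ids)

    blocks = cfg.blocks()
    mask_for = {
        "all": np.ones(n_samples, bool),
        "udca_end": (arm_arr == "UDCA") & is_end,
        "placebo_end": (arm_arr == "placebo") & is_end,
    }
    noise = _block_noise(n_samples, cfg.n_features, blocks, mask_for, rng)

    # designated-genus shifts (panel signal) plus a small consistent push
    # along the community gradient (the signal the paired-PC1 tests detect)
    shift = np.zeros(cfg.n_features)
    genus_of = {fid: tax.at_rank(fid, "genus") for fid in feature_ids}
    for f, fid in enumerate(feature_ids):
        if genus_of[fid] in _SHIFT_GENERA_UP:
            shift[f] = cfg.arm_shift_magnitude
        elif genus_of[fid] in _SHIFT_GENERA_DOWN:
            shift[f] = -cfg.arm_shift_magnitude
    shift = shift + cfg.gradient_shift * phylum_sign

    latent = mu[None, :] + subject_eff[subj_of] + noise
    latent[mask_for["udca_end"]] += shift[None, :]

    # counts ------------------------------------------------------------
    depths = np.maximum(
        cfg.min_depth,
        np.round(rng.lognormal(cfg.depth_log_mean, cfg.depth_log_sigma, n_samples)),
    ).astype(np.int64)
    logits = latent - latent.max(axis=1, keepdims=True)
    probs = np.exp(logits)
    probs /= probs.sum(axis=1, keepdims=True)
    counts = np.empty((n_samples, cfg.n_features), np.int64)
    for s in range(n_samples):
        counts[s] = rng.multinomial(depths[s], probs[s])
    table = FeatureTable(pd.DataFrame(counts, index=sample_ids, columns=feature_ids))

    # outcomes ----------------------------------------------------------
    om = cfg.outcome_model
    hub_pos, hub_neg = cfg.hub_spec.hub_positive, cfg.hub_spec.hub_negative
    lat = pd.DataFrame(latent, index=sample_ids, columns=feature_ids)
    d_pos = np.empty(n_subj)
    d_neg = np.empty(n_subj)
    for i, s in enumerate(subjects):
        d_pos[i] = lat.loc[f"{s}.E"].iloc[hub_pos] - lat.loc[f"{s}.B"].iloc[hub_pos]
        d_neg[i] = lat.loc[f"{s}.E"].iloc[hub_neg] - lat.loc[f"{s}.B"].iloc[hub_neg]
    eta = np.full(n_subj, om.intercept)
    male = sex == "M"
    eta[male] += om.beta_negative_hub * d_neg[male] + om.beta_positive_hub * d_pos[male]
    p_out = 1.0 / (1.0 + np.exp(-eta))
    outcome_any = (rng.random(n_subj) < p_out).astype(int)
    outcome_adv = outcome_any * (rng.random(n_subj) < om.advanced_fraction).astype(int)

    storage = np.where(
        is_end, cfg.storage_mean_end, cfg.storage_mean_baseline
    ) + storage_subject[subj_of] + rng.normal(0.0, cfg.storage_sd / 2, n_samples)

    meta = CohortMetadata(
        pd.DataFrame(
            {
                "subject_id": [subjects[i] for i in subj_of],
                "arm": arm_arr,
                "timepoint": tp_arr,
                "sex": sex[subj_of],
                "age": age[subj_of],
                "aspirin": aspirin[subj_of],
                "batch_mismatch": batch[subj_of],
                "storage_years": np.round(storage, 2),
                "outcome_any": outcome_any[subj_of],
                "outcome_advanced": outcome_adv[subj_of],
            },
            index=sample_ids,
        )
    )

    truth = SimulationTruth(
        latent=lat,
        subject_effects=pd.DataFrame(subject_eff, index=subjects, columns=feature_ids),
        basis_correlation={
            "udca_end": _basis_correlation(cfg.n_features, blocks, "udca_end"),
            "placebo_end": _basis_correlation(cfg.n_features, blocks, "placebo_end"),
        },
        shift=shift,
        outcome_model=om,
        hub_features=(feature_ids[hub_pos], feature_ids[hub_neg]),
        icc_target=cfg.icc_target,
    )
    return table, tree, tax, meta, truth


def write_cohort(outdir, table, tree, tax, meta, truth=None) -> None:
    """Write the five cohort artifacts as plain text into ``outdir``."""
    import os

    from .core_io import write_feature_table, write_metadata, write_taxonomy

    os.makedirs(outdir, exist_ok=True)
    write_feature_table(table, os.path.join(outdir, "feature_table.tsv"))
    tree.write(os.path.join(outdir, "tree.nwk"))
    write_taxonomy(tax, os.path.join(outdir, "taxonomy.tsv"))
    write_metadata(meta, os.path.join(outdir, "metadata.tsv"))
    if truth is not None:
        truth.latent.round(5).to_csv(
            os.path.join(outdir, "truth_latent.tsv"), sep="\t", lineterminator="\n"
        )
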