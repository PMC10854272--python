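"""Two-site synthetic connectome cohorts with controlled site and age effects.

The generator emulates the situation the harmonization pipeline is built for:
two age/sex-matched cohorts of 84-node structural connectomes whose matrices
differ systematically by acquisition site, not biology.

Network model
-------------
Nodes split into two hemispheres and, within each hemisphere, into modules.
Every node pair belongs to one of three blocks — within-module,
between-module same-hemisphere, or inter-hemispheric — with block-specific
connection densities and lognormal base streamline counts (heavy-tailed, like
real tractography counts). The edge skeleton and per-edge base weights are
drawn once per cohort and shared by every subject, so edges are features that
can be compared across subjects, as ComBat assumes.

Subject variation: multiplicative lognormal noise with a configurable
coefficient of variation, plus a linear age trend. By default ageing *reduces
between-module and inter-hemispheric* counts, which makes networks of older
subjects more modular and less integrated — a positive age-modularity and a
negative age-global-efficiency correlation, the direction reported for
normal ageing.

Site effect: site 2 scales its inter-hemispheric counts by a multiplicative
factor (< 1: fewer crossing streamlines) and adds per-edge offsets drawn once
and fixed across subjects; site 1 has longer inter-hemispheric streamlines
than site 2 by a configurable length delta. Both are per-edge location/scale
effects, i.e. exactly the class of artifact ComBat models.

Counts are rounded to integers (streamline counts are integers); lengths are
in mm-equivalent units.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import scipy.stats

from connharm.io import (
    MEAN_LENGTH,
    SITES,
    STREAMLINE_COUNT,
    CohortManifest,
    ConnectivityMatrix,
)
import pandas as pd


@dataclass
class SiteEffect:
    """Site-2 count perturbation and the inter-hemispheric length asymmetry.

    additive_scale : SD (in counts) of per-edge offsets added to site-2 counts,
        drawn once and shared by all site-2 subjects.
    multiplicative_factor : factor on site-2 inter-hemispheric counts
        (< 1 means fewer crossing streamlines at site 2).
    interhemispheric_length_delta : mm by which site-1 inter-hemispheric mean
        streamline lengths exceed site-2's.
    """

    additive_scale: float = 2.0
    multiplicative_factor: float = 0.33
    interhemispheric_length_delta: float = 14.0


@dataclass
class AgeEffect:
    """Linear fractional change of edge counts per year of age (around the cohort mean).

    Ageing weakens long-range integration (between-module and inter-hemispheric
    counts fall) while the few dominant hub connections consolidate; since the
    hubs anchor the max normalization, both trends lower global efficiency and
    raise modularity with age.
    """

    within_slope: float = 0.0
    between_slope: float = -0.0065
    hub_slope: float = 0.008


@dataclass
class SyntheticConfig:
    """Generator settings; packaged defaults are calibrated to the two-site study conditions."""

    n_nodes: int = 84
    n_per_site: int = 84
    n_modules: int = 6
    hemisphere_split: int = 42
    seed: int = 0
    base_count_scale: float = 260.0
    base_length_mm: float = 55.0
    site_effect: SiteEffect = field(default_factory=SiteEffect)
    age_effect: AgeEffect = field(default_factory=AgeEffect)
    noise_cv: float = 0.30
    age_range: tuple[float, float] = (60.0, 89.0)
    age_mean_sd: tuple[float, float] = (72.4, 6.0)
    # block structure calibration (densities and relative weights per block)
    within_density: float = 0.95
    between_density: float = 0.55
    interhemi_density: float = 0.08
    #: total between-module same-hemisphere weight as a fraction of total
    #: within-module weight (fixes the modularity level independent of density)
    between_total_frac: float = 0.11
    #: total inter-hemispheric weight as a fraction of total within-module weight
    interhemi_total_frac: float = 0.145
    weight_sigma: float = 1.75
    #: truncation (in SDs) of the base-weight lognormal tail; keeps the
    #: maximum edge weight, and with it max-normalized efficiency, stable
    weight_zmax: float = 2.0
    #: one hub edge per module is pinned at hub_ratio x the mean within-module
    #: edge weight (the few very strong connections real count matrices have);
    #: this fixes the normalization maximum and thus the efficiency scale
    hub_ratio: float = 30.0
    #: per-subject lognormal variability of overall between-module integration
    subject_between_cv: float = 0.06
    # mean-length model
    interhemi_length_extra: float = 55.0
    length_sd: float = 10.0
    length_noise_cv: float = 0.05

    def __post_init__(self) -> None:
        if self.n_nodes < 4:
            raise ValueError("n_nodes must be >= 4")
        if self.n_modules < 2:
            raise ValueError("n_modules must be >= 2")
        if not (0 < self.hemisphere_split < self.n_nodes):
            raise ValueError("hemisphere_split must lie strictly inside (0, n_nodes)")
        if self.noise_cv <= 0:
            raise ValueError("noise_cv must be > 0")
        if self.n_per_site < 1:
            raise ValueError("n_per_site must be >= 1")
        lo, hi = self.age_range
        if lo > hi:
            raise ValueError("age_range must satisfy min <= max")


@dataclass
class SubjectPair:
    """A matched site1/site2 subject pair (same sex, bounded age difference)."""

    site1_subject_id: str
    site2_subject_id: str
    age_difference: float


def module_labels(config: SyntheticConfig) -> np.ndarray:
    """Module label per node; modules nest inside hemispheres."""
    n, h = config.n_nodes, config.hemisphere_split
    m_left = config.n_modules // 2
    m_right = config.n_modules - m_left
    labels = np.empty(n, dtype=int)
    for part, (start, stop, m) in enumerate(((0, h, m_left), (h, n, m_right))):
        if m == 0:  # degenerate: all modules on the other side
            labels[start:stop] = 0
            continue
        chunks = np.array_split(np.arange(start, stop), m)
        base = 0 if part == 0 else config.n_modules // 2
        for k, nodes in enumerate(chunks):
            labels[nodes] = base + k
    return labels


def _block_types(config: SyntheticConfig) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Upper-triangle (i < j) index arrays and a block code per pair.

    Codes: 0 within-module, 1 between-module same hemisphere, 2 inter-hemispheric.
    """
    n = config.n_nodes
    labels = module_labels(config)
    hemi = (np.arange(n) >= config.hemisphere_split).astype(int)
    iu, ju = np.triu_indices(n, k=1)
    same_module = labels[iu] == labels[ju]
    same_hemi = hemi[iu] == hemi[ju]
    block = np.where(same_module & same_hemi, 0, np.where(same_hemi, 1, 2))
    return iu, ju, block


def sample_demographics(config: SyntheticConfig, rng: np.random.Generator | None = None) -> CohortManifest:
    """Draw a two-site manifest: truncated-normal ages, exactly half female per site."""
    if rng is None:
        rng = np.random.default_rng(config.seed)
    lo, hi = config.age_range
    mean, sd = config.age_mean_sd
    rows = []
    for site in SITES:
        if lo == hi:
            ages = np.full(config.n_per_site, float(lo))
        else:
            a, b = (lo - mean) / sd, (hi - mean) / sd
            ages = scipy.stats.truncnorm.rvs(
                a, b, loc=mean, scale=sd, size=config.n_per_site, random_state=rng
            )
        n_f = config.n_per_site // 2
        sexes = np.array(["F"] * n_f + ["M"] * (config.n_per_site - n_f))
        rng.shuffle(sexes)
        for k in range(config.n_per_site):
            rows.append((f"{site}_s{k + 1:03d}", site, round(float(ages[k]), 2), sexes[k]))
    return CohortManifest(
        pd.DataFrame(rows, columns=["subject_id", "site", "age", "sex"]),
        age_range=(min(lo, 0.0), max(hi, 120.0)),
    )


def _lognormal_factor(rng: np.random.Generator, cv: float, size: int) -> np.ndarray:
    """Multiplicative lognormal noise with coefficient of variation ~cv.

    The tail is truncated at 2.5 SD (log scale) so a single subject's maximum
    edge weight — the anchor of max-normalized efficiency — cannot be driven
    by one extreme noise draw.
    """
    sigma = np.sqrt(np.log1p(cv**2))
    z = scipy.stats.truncnorm.rvs(-4.0, 2.5, size=size, random_state=rng)
    return np.exp(sigma * z - 0.5 * sigma**2)


def generate_cohort(
    config: SyntheticConfig,
) -> tuple[list[ConnectivityMatrix], CohortManifest]:
    """Generate both sites' paired count and length matrices plus the manifest.

    Returns one streamline_count and one mean_length matrix per subject
    (manifest order: all site1, then all site2). Bit-reproducible for a fixed
    config and seed.
    """
    rng = np.random.default_rng(config.seed)
    n = config.n_nodes
    iu, ju, block = _block_types(config)
    n_pairs = iu.size

    # --- cohort-level structure, shared across subjects -------------------
    density = np.array([config.within_density, config.between_density, config.interhemi_density])
    mask = rng.random(n_pairs) < density[block]
    # block total weights: within sets the scale; the two between blocks are
    # fractions of it, so modularity is insensitive to density choices
    n_within = float((block == 0).sum())
    within_total = config.base_count_scale * config.within_density * n_within
    block_total = np.array(
        [within_total, within_total * config.between_total_frac, within_total * config.interhemi_total_frac]
    )
    sigma = config.weight_sigma
    z = scipy.stats.truncnorm.rvs(
        -4.0, config.weight_zmax, size=n_pairs, random_state=rng
    )
    base_w = np.exp(sigma * z) * mask
    # standardize each block's total weight to its target so the within/between
    # weight balance (and with it modularity) does not drift with the
    # particular tail draws of one cohort realization
    for c in range(3):
        sel = (block == c) & mask
        if not sel.any():
            continue
        base_w[sel] *= block_total[c] / base_w[sel].sum()

    # hub edges: pin the strongest masked within-module edge of each module to
    # hub_ratio x the mean within-module edge weight, then restore the within
    # total by rescaling the non-hub within edges
    labels = module_labels(config)
    within_mean = within_total / max(1.0, float(((block == 0) & mask).sum()))
    hub_value = config.hub_ratio * within_mean
    hub_idx = []
    for mod in range(config.n_modules):
        cand = np.flatnonzero((block == 0) & mask & (labels[iu] == mod))
        if cand.size:
            hub_idx.append(cand[np.argmax(base_w[cand])])
    if hub_idx:
        hub_idx = np.array(hub_idx)
        non_hub = (block == 0) & mask
        non_hub[hub_idx] = False
        remaining = within_total - hub_value * hub_idx.size
        if remaining > 0 and non_hub.any():
            base_w[non_hub] *= remaining / base_w[non_hub].sum()
        base_w[hub_idx] = hub_value

    base_len = rng.normal(config.base_length_mm, config.length_sd, size=n_pairs)
    base_len = np.maximum(base_len, 1.0)
    base_len = base_len + np.where(block == 2, config.interhemi_length_extra, 0.0)
    base_len *= mask

    # site-2 count perturbation: fixed per edge, shared by all site-2 subjects
    se = config.site_effect
    site2_offsets = rng.normal(0.0, se.additive_scale, size=n_pairs) * mask
    site2_ih_factor = np.where(block == 2, se.multiplicative_factor, 1.0)
    site1_len = base_len + np.where((block == 2) & mask, se.interhemispheric_length_delta, 0.0)
    site2_len = base_len

    manifest = sample_demographics(config, rng)

    age_ref = config.age_mean_sd[0]
    slope = np.where(
        block == 0, config.age_effect.within_slope, config.age_effect.between_slope
    )
    if len(hub_idx):
        slope[hub_idx] = config.age_effect.hub_slope

    matrices: list[ConnectivityMatrix] = []
    for _, rec in manifest.table.iterrows():
        sid, site, age = rec["subject_id"], rec["site"], float(rec["age"])
        age_factor = np.maximum(0.0, 1.0 + slope * (age - age_ref))
        # subject-level integration: one lognormal factor on all between-module
        # and inter-hemispheric edges (biological between-subject variability)
        integration = _lognormal_factor(rng, config.subject_between_cv, 1)[0]
        w = base_w * age_factor * np.where(block == 0, 1.0, integration)
        if site == SITES[1]:
            w = w * site2_ih_factor
        w = w * _lognormal_factor(rng, config.noise_cv, n_pairs)
        if site == SITES[1]:
            w = w + site2_offsets
        counts = np.maximum(0.0, np.rint(w))
        cm = np.zeros((n, n))
        cm[iu, ju] = counts
        cm[ju, iu] = counts
        matrices.append(ConnectivityMatrix(sid, STREAMLINE_COUNT, cm))

        length = (site1_len if site == SITES[0] else site2_len) * _lognormal_factor(
            rng, config.length_noise_cv, n_pairs
        )
        length = np.where(mask, np.maximum(length, 1.0), 0.0)
        lm = np.zeros((n, n))
        lm[iu, ju] = length
        lm[ju, iu] = length
        matrices.append(ConnectivityMatrix(sid, MEAN_LENGTH, lm))

    return matrices, manifest


def greedy_match(
    a: CohortManifest, b: CohortManifest, max_age_diff: float = 1.0
) -> list[SubjectPair]:
    """Greedy one-to-one pairing of a's subjects with same-sex subjects of b.

    Subjects of ``a`` are visited in manifest order; each takes the unused
    same-sex subject of ``b`` with the smallest absolute age difference
    (earliest ``b`` order wins ties) and the pair is kept only if that
    difference is within ``max_age_diff`` years. Unmatched subjects are
    simply omitted.
    """
    b_rows = list(b.table.itertuples(index=False))
    used = [False] * len(b_rows)
    pairs: list[SubjectPair] = []
    for rec in a.table.itertuples(index=False):
        best_k, best_diff = -1, np.inf
        for k, cand in enumerate(b_rows):
            if used[k] or cand.sex != rec.sex:
                continue
            diff = abs(rec.age - cand.age)
            if diff < best_diff:
                best_k, best_diff = k, diff
        if best_k >= 0 and best_diff <= max_age_diff:
            used[best_k] = True
            pairs.append(
                SubjectPair(
                    site1_subject_id=rec.subject_id,
                    site2_subject_id=b_rows[best_k].subject_id,
                    age_difference=float(rec.age - b_rows[best_k].age),
                )
            )
    return pairs
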