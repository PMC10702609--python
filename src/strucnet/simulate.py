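"""Synthetic two-group streamline-count cohorts and diffusion tables.

The generator emulates the data structure the group-comparison pipeline
assumes: two groups (9 wild-type vs 10 knockout subjects), 72 bilateral
regions, symmetric nonnegative-integer count matrices whose within-hemisphere
totals sit near 5·10⁵ streamlines, heavy zero-inflation on weak long-range
pairs, and a multiplicative knockout deficit concentrated on designated
hippocampus/amygdala edges.

Count model (zero-inflated negative binomial):

1. Edge propensities p_ij are log-normal, drawn once per cohort and shared
   by every subject (anatomy is common to the cohort; subjects differ only
   by sampling noise).  Cross-hemisphere pairs are attenuated (long-range
   tracts are sparser) and designated effect edges are strengthened (the
   affected limbic tracts are major bundles, cf. their share of hemispheric
   totals).
2. Structural zeros: each edge is absent with probability
   π_ij = zero_prob^(p_ij / p̄)  (p̄ = mean within-hemisphere propensity),
   so weak pairs are mostly absent and strong tracts essentially never are.
   The absence mask is drawn once per cohort and shared across subjects —
   in real data the same weak pairs are zero in every animal.  Effect edges
   have the exponent floored (a multiplicative deficit is only defined on a
   tract that exists).
3. Counts: c_ij ~ NegBin(mean = s·p_ij·f, size = dispersion), independent
   across subjects and edges, where f = effect_factor on effect edges for
   knockout subjects and 1 otherwise.  The scale s is calibrated per
   hemisphere so the expected within-hemisphere total (wild-type, given the
   realized absence mask) equals ``target_hemisphere_total`` — each
   hemisphere is seeded with a fixed budget of tracking seeds, so totals are
   calibrated per seeding.

Reproducibility: one cohort-level seed expands into independent substreams
(propensities, absence mask, one per subject) via ``numpy`` SeedSequence
spawning, so cohorts are bit-reproducible and subjects independent.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

from .atlas import RegionAtlas, packaged_atlas
from .connectome import SubjectConnectome
from .tensor import dti_metrics

__all__ = [
    "DEFAULT_EFFECT_EDGES",
    "CohortConfig",
    "draw_propensities",
    "structural_zero_probs",
    "generate_subject",
    "generate_cohort",
    "generate_diffusion_table",
]

# Knockout deficit edges: hippocampus/amygdala pairs of the left hemisphere
# (cortical amygdalar area COA and hippocampal subfields CA1/CA3/DG against
# their main partners).
DEFAULT_EFFECT_EDGES: tuple[tuple[str, str], ...] = (
    ("COA", "CP"), ("COA", "TH"), ("COA", "VS"), ("COA", "CA3"),
    ("COA", "DG"), ("COA", "CC"), ("COA", "HY"), ("CA1", "IntC"),
    ("CA1", "IC"), ("DG", "CP"),
)

# Backbone tracts: dominant, stable bundles (callosal/corticostriatal/
# thalamocortical projections, intra-hippocampal connections, the fimbria
# output and the amygdalo-piriform pathway), mirrored across hemispheres.
# They anchor the max-normalization of every subject's adjacency matrix the
# way the major bundles do in real tractography.
DEFAULT_BACKBONE_EDGES: tuple[tuple[str, str], ...] = (
    ("CC", "ICtx"), ("CP", "ICtx"), ("TH", "ICtx"), ("CC", "CP"),
    ("CA1", "DG"), ("CA3", "DG"), ("CA1", "F"), ("COA", "PIR"),
    ("RCC", "RICtx"), ("RCP", "RICtx"), ("RTH", "RICtx"), ("RCC", "RCP"),
    ("RCA1", "RDG"), ("RCA3", "RDG"), ("RCA1", "RF"), ("RCOA", "RPIR"),
)


@dataclass(frozen=True)
class CohortConfig:
    """Study conditions for one synthetic cohort.

    Defaults mirror the emulated study: 9 WT vs 10 KO subjects, 5·10⁵
    expected streamlines per hemisphere, overdispersed counts
    (negative-binomial size 10 reproduces the few-percent coefficient of
    variation of hemispheric totals), a 0.5× knockout deficit on ten
    hippocampus/amygdala edges, and structural absence of roughly half of
    the average-strength pairs (zero_prob), concentrated on weak ones.
    """

    n_wt: int = 9
    n_ko: int = 10
    atlas: RegionAtlas | None = None  # None → packaged 72-region atlas
    propensity_log_mean: float = 0.0
    propensity_log_sd: float = 1.0
    dispersion: float = 10.0
    zero_prob: float = 0.5
    target_hemisphere_total: float = 5e5
    cross_hemisphere_factor: float = 0.3
    effect_edges: tuple[tuple[str, str], ...] = DEFAULT_EFFECT_EDGES
    effect_factor: float = 0.5
    effect_edge_strength: float = 4.0
    effect_edge_min_presence: float = 8.0
    backbone_edges: tuple[tuple[str, str], ...] = DEFAULT_BACKBONE_EDGES
    backbone_strength: float = 20.0
    rng_seed: int = 0

    def __post_init__(self) -> None:
        if self.n_wt < 2 or self.n_ko < 2:
            raise ValueError("each group needs at least 2 subjects")
        if not 0.0 <= self.zero_prob <= 1.0:
            raise ValueError("zero_prob must be in [0, 1]")
        if self.effect_factor <= 0:
            raise ValueError("effect_factor must be > 0")
        if self.dispersion <= 0:
            raise ValueError("dispersion must be > 0")

    def resolved_atlas(self) -> RegionAtlas:
        return self.atlas if self.atlas is not None else packaged_atlas()

    def null(self) -> "CohortConfig":
        """The same conditions without a group effect (effect_factor = 1)."""
        return replace(self, effect_factor=1.0)


def _pair_masks(atlas: RegionAtlas):
    """(within-hemisphere mask, cross-hemisphere mask) over the full matrix."""
    n = len(atlas)
    left = np.zeros(n, dtype=bool)
    left[atlas.hemisphere_indices("L")] = True
    within = np.outer(left, left) | np.outer(~left, ~left)
    np.fill_diagonal(within, False)
    cross = np.outer(left, ~left) | np.outer(~left, left)
    return within, cross


def _edge_mask(edges, atlas: RegionAtlas) -> np.ndarray:
    mask = np.zeros((len(atlas), len(atlas)), dtype=bool)
    for a, b in edges:
        i, j = atlas.index_of(a), atlas.index_of(b)
        if i == j:
            raise ValueError(f"edge ({a}, {b}) is a self-loop")
        mask[i, j] = mask[j, i] = True
    return mask


def _effect_mask(config: CohortConfig, atlas: RegionAtlas) -> np.ndarray:
    return _edge_mask(config.effect_edges, atlas)


def draw_propensities(config: CohortConfig, rng: np.random.Generator) -> np.ndarray:
    """Cohort-level symmetric edge propensities (relative mean strengths)."""
    atlas = config.resolved_atlas()
    n = len(atlas)
    iu, ju = np.triu_indices(n, k=1)
    vals = rng.lognormal(config.propensity_log_mean, config.propensity_log_sd,
                         size=iu.size)
    p = np.zeros((n, n))
    p[iu, ju] = vals
    p += p.T
    _, cross = _pair_masks(atlas)
    p[cross] *= config.cross_hemisphere_factor
    p[_effect_mask(config, atlas)] *= config.effect_edge_strength
    p[_edge_mask(config.backbone_edges, atlas)] *= config.backbone_strength
    return p


def structural_zero_probs(propensities: np.ndarray, config: CohortConfig) -> np.ndarray:
    """Per-edge structural-absence probability π_ij = zero_prob^(p_ij/p̄)."""
    atlas = config.resolved_atlas()
    p = np.asarray(propensities, dtype=float)
    within, _ = _pair_masks(atlas)
    ref = p[within].mean() if within.any() else 0.0
    with np.errstate(divide="ignore"):
        expo = p / ref if ref > 0 else np.zeros_like(p)
    present = _effect_mask(config, atlas) | _edge_mask(config.backbone_edges, atlas)
    expo = np.where(present, np.maximum(expo, config.effect_edge_min_presence), expo)
    # 0**0 = 1: absent propensity ⇒ structurally zero, for any zero_prob
    return np.power(config.zero_prob, expo)


def _draw_structural_zeros(pi: np.ndarray, rng: np.random.Generator) -> np.ndarray:
    n = pi.shape[0]
    iu, ju = np.triu_indices(n, k=1)
    hit = rng.random(iu.size) < pi[iu, ju]
    mask = np.zeros((n, n), dtype=bool)
    mask[iu, ju] = hit
    mask |= mask.T
    return mask


def _hemisphere_scales(p_eff: np.ndarray, config: CohortConfig,
                       atlas: RegionAtlas) -> np.ndarray:
    """Per-edge scale matrix: each hemisphere calibrated to the target total,
    cross-hemisphere edges at the geometric mean of the two scales."""
    n = len(atlas)
    scale = np.zeros((n, n))
    s_by_side = {}
    for side in ("L", "R"):
        idx = atlas.hemisphere_indices(side)
        block = p_eff[np.ix_(idx, idx)]
        tot = np.triu(block, k=1).sum()
        s_by_side[side] = config.target_hemisphere_total / tot if tot > 0 else 0.0
        scale[np.ix_(idx, idx)] = s_by_side[side]
    _, cross = _pair_masks(atlas)
    scale[cross] = np.sqrt(s_by_side["L"] * s_by_side["R"])
    return scale


def generate_subject(
    config: CohortConfig,
    propensities: np.ndarray,
    group: str,
    rng: np.random.Generator,
    structural_zeros: np.ndarray | None = None,
    subject_id: str = "S0",
) -> SubjectConnectome:
    """Draw one subject's count matrix from the cohort propensities.

    ``structural_zeros`` is the cohort's shared absence mask; when omitted
    (direct calls) a mask is drawn from ``rng`` with the model's π_ij.
    """
    p = np.asarray(propensities, dtype=float)
    if np.any(p < 0) or not np.allclose(p, p.T):
        raise ValueError("propensities must be symmetric and nonnegative")
    atlas = config.resolved_atlas()
    if p.shape != (len(atlas), len(atlas)):
        raise ValueError("propensity matrix does not match atlas size")
    if structural_zeros is None:
        structural_zeros = _draw_structural_zeros(structural_zero_probs(p, config), rng)
    p_eff = np.where(structural_zeros, 0.0, p)
    np.fill_diagonal(p_eff, 0.0)
    mean = _hemisphere_scales(p_eff, config, atlas) * p_eff
    if group == "KO":
        eff = _effect_mask(config, atlas)
        mean = np.where(eff, mean * config.effect_factor, mean)

    n = mean.shape[0]
    iu, ju = np.triu_indices(n, k=1)
    m = mean[iu, ju]
    k = config.dispersion
    counts_flat = np.zeros(m.size, dtype=np.int64)
    pos = m > 0
    counts_flat[pos] = rng.negative_binomial(k, k / (k + m[pos]))
    counts = np.zeros((n, n), dtype=np.int64)
    counts[iu, ju] = counts_flat
    counts += counts.T
    return SubjectConnectome(subject_id=subject_id, group=group, counts=counts)


def generate_cohort(config: CohortConfig) -> list[SubjectConnectome]:
    """One cohort: shared propensities and absence mask, independent subjects.

    Returns ``n_wt`` wild-type then ``n_ko`` knockout subjects, reproducible
    from ``config.rng_seed``.
    """
    n_total = config.n_wt + config.n_ko
    streams = np.random.SeedSequence(config.rng_seed).spawn(2 + n_total)
    p = draw_propensities(config, np.random.default_rng(streams[0]))
    mask = _draw_structural_zeros(structural_zero_probs(p, config),
                                  np.random.default_rng(streams[1]))
    subjects = []
    for i in range(n_total):
        group = "WT" if i < config.n_wt else "KO"
        within = i if group == "WT" else i - config.n_wt
        subjects.append(generate_subject(
            config, p, group, np.random.default_rng(streams[2 + i]),
            structural_zeros=mask,
            subject_id=f"{group.lower()}{within + 1:02d}",
        ))
    return subjects


# -- diffusion-scalar tables -------------------------------------------------

def generate_diffusion_table(
    config: CohortConfig,
    fa_shift: float = 0.0,
    rng_seed: int | None = None,
) -> pd.DataFrame:
    """Per-subject per-ROI diffusion scalars with optional group FA effect.

    Each homolog region pair shares a baseline (FA ~ U(0.1, 0.4), MD around
    5·10⁻⁴ mm²/s, log-normal volume around 4 mm³); subjects add independent
    noise and knockout subjects an additive ``fa_shift`` on FA.  Eigenvalue
    triples are built axially symmetric from (FA, MD) and the scalar metrics
    recomputed from them, so FA ∈ [0,1] and AD ≥ MD ≥ RD hold by
    construction.  Left/right homologs share baselines, making
    left-vs-right comparisons null when ``fa_shift = 0``.
    """
    atlas = config.resolved_atlas()
    seed = config.rng_seed if rng_seed is None else rng_seed
    rng = np.random.default_rng(np.random.SeedSequence((seed, 0xD1F)))
    left = atlas.hemisphere_subset("L")
    base_fa = rng.uniform(0.1, 0.4, size=len(left))
    base_md = rng.normal(5e-4, 3e-5, size=len(left))
    base_vol = rng.lognormal(np.log(4.0), 0.6, size=len(left))
    pair_of = {}  # abbreviation → baseline row
    for i, reg in enumerate(left):
        pair_of[reg.abbreviation] = i
        pair_of[atlas.homolog(reg.abbreviation)] = i

    groups = ["WT"] * config.n_wt + ["KO"] * config.n_ko
    rows = []
    for s_idx, group in enumerate(groups):
        within = s_idx if group == "WT" else s_idx - config.n_wt
        sid = f"{group.lower()}{within + 1:02d}"
        for reg in atlas.regions:
            b = pair_of[reg.abbreviation]
            fa = base_fa[b] + rng.normal(0.0, 0.02)
            if group == "KO":
                fa += fa_shift
            md = base_md[b] * rng.lognormal(0.0, 0.05)
            vol = base_vol[b] * rng.lognormal(0.0, 0.10)
            rows.append((sid, group, reg.abbreviation, reg.hemisphere, vol, fa, md))
    df = pd.DataFrame(rows, columns=["subject_id", "group", "roi", "hemisphere",
                                     "volume_mm3", "_fa", "_md"])
    if (df["_fa"] < 0).any() or (df["_fa"] > 1).any():
        raise ValueError("fa_shift drives FA outside [0, 1]")
    # axially symmetric tensor: λ1 = MD(1+2δ), λ2 = λ3 = MD(1−δ),
    # δ = FA / sqrt(3 − 2 FA²)
    fa = df["_fa"].to_numpy()
    md = df["_md"].to_numpy()
    delta = fa / np.sqrt(3.0 - 2.0 * fa**2)
    lam = np.column_stack([md * (1 + 2 * delta), md * (1 - delta), md * (1 - delta)])
    m = dti_metrics(lam)
    out = df[["subject_id", "group", "roi", "hemisphere", "volume_mm3"]].copy()
    out["FA"], out["MD"], out["AD"], out["RD"] = m.FA, m.MD, m.AD, m.RD
    return out
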