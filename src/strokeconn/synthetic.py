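"""Synthetic group connectome datasets and the embedded patient table.

The generator emulates the study conditions of a chronic-stroke vs.
healthy-control comparison: two groups of 13 subjects, 80-ROI symmetric
sparse connectomes, optional planted edge-level group differences of
configurable magnitude, and clinical scores that depend monotonically on a
chosen nodal metric plus noise.  Everything is reproducible from a single
integer seed.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np

from .connectome import ConnectomeSet, resample_cw

logger = logging.getLogger(__name__)

ARAT_MAX = 57
FMA_UE_MAX = 60
FMA_SE_MAX = 42   # shoulder/elbow portion of the upper-extremity scale
FMA_WH_MAX = 24   # wrist/hand portion


@dataclass(frozen=True)
class SubjectRecord:
    """One subject's metadata row; healthy controls carry missing clinical fields."""

    subject_id: str
    group: str                          # "stroke" | "healthy"
    lesion_side: str = "none"           # "L" | "R" | "none"
    time_since_stroke: float | None = None   # years
    age_range: str | None = None
    sex: str | None = None
    handedness: str | None = None
    stroke_type: str | None = None      # "i" ischemic | "h" hemorrhagic
    lesion_locations: tuple[str, ...] = ()
    arat: int | None = None
    fma_ue: int | None = None
    fma_se: int | None = None
    fma_wh: int | None = None
    plic_fa_ipsi: float | None = None


@dataclass(frozen=True)
class ScoreLink:
    """Monotone link from a nodal metric to a clinical score: a + b*m + noise."""

    target_roi: int
    slope: float
    intercept: float
    noise_sd: float

    def __post_init__(self) -> None:
        if self.noise_sd < 0:
            raise ValueError("noise_sd must be >= 0")


@dataclass(frozen=True)
class EffectSpec:
    n_per_group: int = 13
    n_rois: int = 80
    target_edges: tuple[tuple[int, int], ...] = ()
    edge_shift: float = 0.0             # additive, raw-CW matrix units
    score_link: ScoreLink | None = None
    edge_density: float = 0.3           # fraction of possible edges kept
    support_jitter: float = 0.02        # per-subject edge flip probability

    def __post_init__(self) -> None:
        if self.n_rois < 4:
            raise ValueError("n_rois must be >= 4")
        if not np.isfinite(self.edge_shift):
            raise ValueError("edge_shift must be finite")
        for i, j in self.target_edges:
            if i == j:
                raise ValueError(f"target edge ({i},{j}) is a self-pair")
            if not (0 <= i < self.n_rois and 0 <= j < self.n_rois):
                raise ValueError(f"target edge ({i},{j}) outside 0..{self.n_rois - 1}")
        if self.score_link is not None and not (
            0 <= self.score_link.target_roi < self.n_rois
        ):
            raise ValueError("score_link.target_roi outside ROI range")


def _symmetrize(upper_vals: np.ndarray, iu, n: int) -> np.ndarray:
    m = np.zeros((n, n))
    m[iu] = upper_vals
    return m + m.T


def _mirror_edge_permutation(n: int, iu) -> np.ndarray:
    """Edge-index permutation induced by the homotopic node map i -> i +/- n/2."""
    h = n // 2
    edge_index = {(i, j): k for k, (i, j) in enumerate(zip(*iu))}
    perm = np.empty(len(iu[0]), dtype=int)
    for k, (i, j) in enumerate(zip(*iu)):
        mi, mj = (i + h) % n, (j + h) % n
        perm[k] = edge_index[(min(mi, mj), max(mi, mj))]
    return perm


def _subject_support(base: np.ndarray, jitter: float, rng: np.random.Generator,
                     forced: np.ndarray) -> np.ndarray:
    """Base support with a small fraction of edges flipped; forced edges kept."""
    flip = rng.random(base.shape) < jitter
    sup = np.where(flip, ~base, base)
    sup[forced] = True
    return sup


def make_group_dataset(
    spec: EffectSpec, rng_seed: int
) -> tuple[list[ConnectomeSet], list[SubjectRecord]]:
    """Generate the two-group synthetic cohort.

    Baseline raw connection weights are i.i.d. log-normal (meanlog 0,
    sdlog 1) on a shared sparse support (per-subject jitter aside); FA
    edges are Beta(5, 3) rescaled to [0.2, 0.7], a plausible white-matter
    range.  Stroke-group target edges get ``edge_shift`` added to the raw
    CW; stroke clinical scores follow ``score_link`` applied to the
    connection strength (CS) of the target ROI, clipped to the score range.

    Matrices are emitted in the ipsilesional-left *analysis* convention:
    right-lesion stroke subjects are marked ``flipped=True`` as if the
    homotopic flip had already been applied, so planted effects sit at the
    stated indices for every subject and downstream stages must not flip
    again.  The shared support is hemispherically mirror-symmetric (for
    even ``n_rois``), as the flip of real native-space data requires.
    """
    rng = np.random.default_rng(rng_seed)
    n = spec.n_rois
    iu = np.triu_indices(n, k=1)
    n_edges = len(iu[0])

    u = rng.random(n_edges)
    if n % 2 == 0:
        # structural support is hemispherically mirror-symmetric, so the
        # later homotopic flip of right-lesion subjects is support-neutral
        mirror = _mirror_edge_permutation(n, iu)
        u = np.where(np.arange(n_edges) <= mirror, u, u[mirror])
    base_support = u < spec.edge_density
    if base_support.sum() < 2:
        base_support[:2] = True
    target_mask = np.zeros(n_edges, dtype=bool)
    if spec.target_edges:
        edge_index = {(min(i, j), max(i, j)): k
                      for k, (i, j) in enumerate(zip(*iu))}
        for e in spec.target_edges:
            target_mask[edge_index[(min(e), max(e))]] = True
    # force targets (and their mirrors, to keep the support symmetric) into
    # every subject's support; the shift itself touches only the targets
    forced = target_mask.copy()
    if spec.target_edges and n % 2 == 0:
        forced = forced | forced[_mirror_edge_permutation(n, iu)]

    connectomes: list[ConnectomeSet] = []
    records: list[SubjectRecord] = []
    stroke_metric_values: list[float] = []

    for g, group in enumerate(("stroke", "healthy")):
        for s in range(spec.n_per_group):
            sup = _subject_support(base_support, spec.support_jitter, rng, forced)
            k = int(sup.sum())
            cw_vals = np.zeros(n_edges)
            fa_vals = np.zeros(n_edges)
            cnt_vals = np.zeros(n_edges)
            len_vals = np.zeros(n_edges)
            cw_vals[sup] = rng.lognormal(0.0, 1.0, size=k)
            fa_vals[sup] = 0.2 + 0.5 * rng.beta(5.0, 3.0, size=k)
            cnt_vals[sup] = rng.poisson(20.0, size=k) + 1
            len_vals[sup] = rng.uniform(20.0, 100.0, size=k)
            if group == "stroke" and spec.target_edges:
                cw_vals[target_mask] += spec.edge_shift
                neg = target_mask & (cw_vals <= 0)
                if neg.any():
                    logger.warning(
                        "edge_shift drove %d raw CW values non-positive; "
                        "clipped to a small positive weight", int(neg.sum())
                    )
                    cw_vals[neg] = 1e-6
            bad_fa = (fa_vals < 0) | (fa_vals > 1)
            if bad_fa.any():
                logger.warning("clipped %d FA edges to [0, 1]", int(bad_fa.sum()))
                fa_vals = np.clip(fa_vals, 0.0, 1.0)

            cs = ConnectomeSet(
                subject_id=f"{group[:1]}{s + 1:02d}",
                fa_matrix=_symmetrize(fa_vals, iu, n),
                count_matrix=_symmetrize(cnt_vals, iu, n),
                meanlen_matrix=_symmetrize(len_vals, iu, n),
                cw_matrix=_symmetrize(cw_vals, iu, n),
            )
            cs.cw_resampled = resample_cw(cs.cw_matrix)
            cs.validate()
            connectomes.append(cs)

            if group == "stroke":
                lesion_side = "R" if rng.random() < 9 / 13 else "L"
                if lesion_side == "R":
                    # analysis convention: right-lesion data arrive flipped
                    cs.flipped = True
                    cs.meta["hemisphere_flipped"] = True
                plic = float(np.clip(rng.normal(0.45, 0.05), 0.2, 0.8))
                if spec.score_link is not None:
                    m = float(cs.cw_resampled[spec.score_link.target_roi].sum())
                    stroke_metric_values.append(m)
                    raw = (spec.score_link.intercept
                           + spec.score_link.slope * m
                           + rng.normal(0.0, spec.score_link.noise_sd))
                    arat = int(np.clip(round(raw), 0, ARAT_MAX))
                    fma_ue = int(np.clip(round(raw * FMA_UE_MAX / ARAT_MAX
                                               + rng.normal(0.0, 1.0)), 0, FMA_UE_MAX))
                else:
                    arat = int(rng.integers(0, ARAT_MAX + 1))
                    fma_ue = int(rng.integers(0, FMA_UE_MAX + 1))
                fma_se = int(np.clip(round(fma_ue * 0.7 + rng.normal(0, 1)), 0, FMA_SE_MAX))
                fma_wh = int(np.clip(round(fma_ue * 0.3 + rng.normal(0, 1)), 0, FMA_WH_MAX))
                records.append(SubjectRecord(
                    subject_id=cs.subject_id, group=group, lesion_side=lesion_side,
                    time_since_stroke=float(np.round(rng.uniform(0.7, 11.0), 1)),
                    sex="M" if rng.random() < 12 / 13 else "F", handedness="R",
                    stroke_type="i" if rng.random() < 0.5 else "h",
                    arat=arat, fma_ue=fma_ue, fma_se=fma_se, fma_wh=fma_wh,
                    plic_fa_ipsi=plic,
                ))
            else:
                records.append(SubjectRecord(
                    subject_id=cs.subject_id, group=group,
                    sex="M" if rng.random() < 6 / 13 else "F", handedness="R",
                ))

    return connectomes, records


def gaussian_null_groups(
    n_per_group: int, n_nodes: int, rng: np.random.Generator
) -> tuple[np.ndarray, np.ndarray]:
    """Two groups of symmetric matrices with i.i.d. standard-normal edges.

    Returns two arrays of shape ``(n_per_group, n_nodes, n_nodes)`` with
    zero diagonals — the global-null substrate for FWER calibration of the
    network-based statistic.
    """
    iu = np.triu_indices(n_nodes, k=1)
    out = []
    for _ in range(2):
        mats = np.zeros((n_per_group, n_nodes, n_nodes))
        vals = rng.standard_normal((n_per_group, len(iu[0])))
        mats[:, iu[0], iu[1]] = vals
        mats += mats.transpose(0, 2, 1)
        out.append(mats)
    return out[0], out[1]


def noise_sd_for_spearman(target_rho: float, slope: float, metric_sd: float) -> float:
    """Noise SD giving a population Spearman of ``target_rho`` for a linear link.

    Uses the bivariate-normal relation rho_s = (6/pi) * arcsin(r/2) to find
    the Pearson r matching the desired Spearman, then solves
    ``r = |b| sd_m / sqrt(b^2 sd_m^2 + sd_e^2)`` for the noise SD.
    """
    if not (0 < target_rho < 1):
        raise ValueError("target_rho must be in (0, 1)")
    r = 2.0 * np.sin(np.pi * target_rho / 6.0)
    return float(abs(slope) * metric_sd * np.sqrt(1.0 / r**2 - 1.0))


# ---------------------------------------------------------------------------
# Embedded demographic table of the 13-patient chronic-stroke cohort.
# Columns: time since stroke (y), age range, sex, lesion side, handedness,
# stroke type (i/h), lesion locations, ARAT, FMA-UE, FMA-SE, FMA-WH.
_TABLE1 = (
    (11.0, "55-59", "M", "R", "R", "i", ("Brainstem",), 28, 24, 17, 7),
    (7.0, "55-59", "M", "R", "R", "i", ("Insula", "IFG", "PUT", "RO", "TP"), 14, 20, 15, 5),
    (3.0, "50-54", "F", "L", "R", "h", ("Insula", "RO", "PUT"), 19, 34, 22, 12),
    (11.0, "60-64", "M", "L", "R", "i", ("PLIC", "PUT"), 15, 22, 17, 5),
    (1.0, "50-54", "M", "L", "R", "i", ("PUT", "CN"), 15, 24, 17, 7),
    (1.0, "65-69", "M", "R", "R", "h", ("Insula", "ITG", "IOG", "PUT"), 8, 13, 10, 3),
    (5.0, "40-44", "M", "R", "R", "h", ("Insula", "RO", "IFG", "STG", "PUT", "TP"), 9, 15, 11, 4),
    (3.0, "40-44", "M", "R", "R", "h", ("Insula", "MTG", "STG", "PUT", "TP", "RO"), 11, 17, 10, 7),
    (1.0, "45-49", "M", "R", "R", "i", ("MFG", "SFG", "precentral", "SMAR", "SMA"), 3, 19, 14, 5),
    (0.67, "45-49", "M", "R", "R", "h", ("ITG", "MTG", "STG", "MOG", "angular", "SMAR"), 16, 17, 13, 4),
    (8.0, "65-69", "M", "L", "R", "h", ("Insula", "PUT", "IFG", "TP"), 10, 22, 19, 3),
    (1.0, "45-49", "M", "R", "R", "h", ("Insula", "PUT"), 12, 34, 24, 10),
    (3.0, "60-64", "M", "R", "R", "i", ("Insula", "PUT", "RO", "IFG"), 4, 16, 12, 4),
)


def table1_fixture() -> tuple[SubjectRecord, ...]:
    """The 13 stroke patients of the study cohort, verbatim."""
    return tuple(
        SubjectRecord(
            subject_id=f"p{i + 1:02d}", group="stroke",
            time_since_stroke=tss, age_range=age, sex=sex, lesion_side=side,
            handedness=hand, stroke_type=stype, lesion_locations=locs,
            arat=arat, fma_ue=ue, fma_se=se, fma_wh=wh,
        )
        for i, (tss, age, sex, side, hand, stype, locs, arat, ue, se, wh)
        in enumerate(_TABLE1)
    )
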