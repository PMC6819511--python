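"""Connectome construction from labeled fibers and nodal network metrics.

The edge measures follow the standard anatomical-connectivity definitions:
the FA matrix holds the average fractional anisotropy of the fibers linking
two regions, and the connection weight (CW) between regions ``u`` and ``v``
with surface sizes ``S_u``, ``S_v`` is

    CW(u, v) = 2 / (S_u + S_v) * sum_{f in F(u,v)} 1 / l(f)

where ``F(u, v)`` is the set of fibers connecting the two regions and
``l(f)`` the length of fiber ``f``.  Raw CWs are then re-sampled, per
subject, onto a Gaussian with mean 0.5 and SD 0.1 via a rank-based
inverse-normal transform so that subjects with very different global fiber
counts become comparable.  Nodal metrics are plain row sums: regional FA
(rFA) over the FA matrix and connection strength (CS) over the re-sampled
CW matrix.
"""

from __future__ import annotations

import importlib.resources
import logging
from dataclasses import dataclass, field, replace
from typing import Iterable

import numpy as np
import pandas as pd
from scipy import stats as sps

from .tracking import Streamline

logger = logging.getLogger(__name__)

SUBNETWORKS = ("DMN", "ATT", "VRN", "ADN", "SMA", "SN")


@dataclass(frozen=True)
class ROI:
    label: int
    name: str
    hemisphere: str          # "L" or "R"
    tissue: str              # "cortical" or "subcortical"
    surface_size: float      # mm^2 (or phantom units)
    subnetwork: str          # one of SUBNETWORKS
    homotopic_label: int


@dataclass(frozen=True)
class Parcellation:
    """Ordered ROI table with a homotopic (mirror-hemisphere) involution."""

    rois: tuple[ROI, ...]

    def __post_init__(self) -> None:
        labels = [r.label for r in self.rois]
        if len(set(labels)) != len(labels):
            raise ValueError("duplicate ROI labels in parcellation")
        by_label = {r.label: r for r in self.rois}
        for r in self.rois:
            if r.surface_size <= 0:
                raise ValueError(f"ROI {r.label} has non-positive surface size")
            partner = by_label.get(r.homotopic_label)
            if partner is None or partner.homotopic_label != r.label:
                raise ValueError(
                    f"homotopic map is not an involution at ROI {r.label}"
                )
            if r.subnetwork not in SUBNETWORKS:
                raise ValueError(
                    f"ROI {r.label} has unknown subnetwork {r.subnetwork!r}"
                )

    def __len__(self) -> int:
        return len(self.rois)

    @property
    def labels(self) -> np.ndarray:
        return np.array([r.label for r in self.rois])

    @property
    def names(self) -> list[str]:
        return [r.name for r in self.rois]

    def index_of(self, label: int) -> int:
        try:
            return int(np.nonzero(self.labels == label)[0][0])
        except IndexError:
            raise KeyError(f"no ROI with label {label}") from None

    @property
    def surface_sizes(self) -> np.ndarray:
        return np.array([r.surface_size for r in self.rois])

    def homotopic_permutation(self) -> np.ndarray:
        """Index permutation mapping each ROI to its mirror-hemisphere partner."""
        label_to_idx = {r.label: i for i, r in enumerate(self.rois)}
        return np.array([label_to_idx[r.homotopic_label] for r in self.rois])

    def subnetwork_blocks(self) -> dict[tuple[str, str], list[int]]:
        """Partition ROI indices into (subnetwork, hemisphere) blocks."""
        blocks: dict[tuple[str, str], list[int]] = {}
        for i, r in enumerate(self.rois):
            blocks.setdefault((r.subnetwork, r.hemisphere), []).append(i)
        return blocks

    @classmethod
    def from_tsv(cls, path) -> "Parcellation":
        df = pd.read_csv(path, sep="\t")
        required = {"label", "name", "hemisphere", "tissue", "surface_size",
                    "subnetwork", "homotopic_label"}
        missing = required - set(df.columns)
        if missing:
            raise ValueError(f"parcellation table missing columns: {sorted(missing)}")
        rois = tuple(
            ROI(int(row.label), str(row.name), str(row.hemisphere),
                str(row.tissue), float(row.surface_size), str(row.subnetwork),
                int(row.homotopic_label))
            for row in df.itertuples(index=False)
        )
        return cls(rois)

    @classmethod
    def default_80(cls) -> "Parcellation":
        """The shipped 80-ROI atlas: 68 cortical + 12 subcortical regions.

        The ROI -> subnetwork assignment is a documented reconstruction of a
        functional regrouping into default-mode (DMN), attention (ATT),
        visual-recognition (VRN), auditory (ADN), sensory-motor (SMA) and
        subcortical (SN) subnetworks per hemisphere; pass a custom table to
        :meth:`from_tsv` to override it.
        """
        ref = importlib.resources.files("strokeconn.data") / "parcellation_dk80.tsv"
        with importlib.resources.as_file(ref) as p:
            parc = cls.from_tsv(p)
        n_cort = sum(r.tissue == "cortical" for r in parc.rois)
        n_sub = sum(r.tissue == "subcortical" for r in parc.rois)
        if (n_cort, n_sub) != (68, 12):
            raise ValueError(
                f"standard atlas must have 68 cortical + 12 subcortical ROIs, "
                f"got {n_cort} + {n_sub}"
            )
        return parc

    @classmethod
    def toy(cls, n_per_hemisphere: int = 3, surface_size: float = 1.0) -> "Parcellation":
        """Tiny 2*n-ROI parcellation for tests; labels 1..2n, L block first."""
        n = n_per_hemisphere
        rois = []
        for h, hemi in enumerate(("L", "R")):
            for i in range(n):
                lab = h * n + i + 1
                rois.append(ROI(
                    label=lab, name=f"roi{i + 1}_{hemi}", hemisphere=hemi,
                    tissue="cortical", surface_size=surface_size,
                    subnetwork=SUBNETWORKS[i % len(SUBNETWORKS)],
                    homotopic_label=lab + (n if hemi == "L" else -n),
                ))
        return cls(tuple(rois))


@dataclass
class ConnectomeSet:
    """Per-subject symmetric connectivity matrices sharing a sparsity support.

    All matrices are dense ``n x n`` with exact symmetry and zero diagonal;
    an entry is structurally zero in every matrix if no fiber joins the pair.
    """

    subject_id: str
    fa_matrix: np.ndarray        # mean per-fiber FA, entries in [0, 1]
    count_matrix: np.ndarray     # |F(u, v)|
    meanlen_matrix: np.ndarray   # mean fiber length
    cw_matrix: np.ndarray        # Eq. above
    cw_resampled: np.ndarray | None = None
    flipped: bool = False
    meta: dict = field(default_factory=dict)

    @property
    def n_rois(self) -> int:
        return self.fa_matrix.shape[0]

    def validate(self) -> None:
        mats = {
            "fa_matrix": self.fa_matrix, "count_matrix": self.count_matrix,
            "meanlen_matrix": self.meanlen_matrix, "cw_matrix": self.cw_matrix,
        }
        support = self.cw_matrix != 0
        for name, m in mats.items():
            if m.shape != self.cw_matrix.shape:
                raise ValueError(f"{name} shape mismatch")
            if not np.array_equal(m, m.T):
                raise ValueError(f"{name} is not exactly symmetric")
            if np.diag(m).any():
                raise ValueError(f"{name} has nonzero diagonal")
            if not np.array_equal(m != 0, support):
                raise ValueError(f"{name} support differs from cw_matrix")
        if self.cw_resampled is not None:
            if not np.array_equal(self.cw_resampled != 0, support):
                raise ValueError("cw_resampled support differs from cw_matrix")


def build_matrices(
    labeled_fibers: Iterable[Streamline],
    parcellation: Parcellation,
    subject_id: str = "",
) -> ConnectomeSet:
    """Accumulate labeled streamlines into FA/count/mean-length/CW matrices.

    Fibers lacking two distinct valid ROI labels are ignored (they were
    already flagged at endpoint assignment); zero-length fibers would divide
    by zero in the CW sum and are rejected with a count.
    """
    n = len(parcellation)
    label_to_idx = {r.label: i for i, r in enumerate(parcellation.rois)}
    S = parcellation.surface_sizes

    fa_sum = np.zeros((n, n))
    len_sum = np.zeros((n, n))
    inv_len_sum = np.zeros((n, n))
    count = np.zeros((n, n), dtype=int)
    n_zero_length = 0

    for f in labeled_fibers:
        if f.endpoint_labels is None:
            continue
        a, b = f.endpoint_labels
        if a == b or a not in label_to_idx or b not in label_to_idx:
            continue
        if f.length <= 0:
            n_zero_length += 1
            continue
        i, j = label_to_idx[a], label_to_idx[b]
        count[i, j] += 1
        fa_sum[i, j] += f.mean_fa
        len_sum[i, j] += f.length
        inv_len_sum[i, j] += 1.0 / f.length

    if n_zero_length:
        logger.warning("rejected %d zero-length fibers", n_zero_length)

    # fold the two triangles together, then mirror
    count = count + count.T
    fa_sum = fa_sum + fa_sum.T
    len_sum = len_sum + len_sum.T
    inv_len_sum = inv_len_sum + inv_len_sum.T

    with np.errstate(invalid="ignore", divide="ignore"):
        fa = np.where(count > 0, fa_sum / np.maximum(count, 1), 0.0)
        meanlen = np.where(count > 0, len_sum / np.maximum(count, 1), 0.0)
    cw = (2.0 / np.add.outer(S, S)) * inv_len_sum
    np.fill_diagonal(cw, 0.0)
    np.fill_diagonal(fa, 0.0)
    np.fill_diagonal(meanlen, 0.0)
    np.fill_diagonal(count, 0)

    cs = ConnectomeSet(
        subject_id=subject_id, fa_matrix=fa, count_matrix=count,
        meanlen_matrix=meanlen, cw_matrix=cw,
        meta={"n_zero_length_rejected": n_zero_length},
    )
    cs.validate()
    return cs


def resample_cw(cw_matrix: np.ndarray) -> np.ndarray:
    """Rank-based inverse-normal re-normalization of the nonzero edges.

    The nonzero upper-triangle entries are ranked (ties get the average
    rank) and the entry of rank ``r`` among ``n`` is mapped to
    ``0.5 + 0.1 * Phi^{-1}((r - 0.5) / n)``, a Blom-type offset that keeps
    quantiles finite and makes the transform exactly symmetric around the
    median.  Structural zeros remain zero; the result is symmetrized.
    """
    cw = np.asarray(cw_matrix, dtype=float)
    if not np.array_equal(cw, cw.T):
        raise ValueError("cw_matrix must be symmetric")
    iu = np.triu_indices(cw.shape[0], k=1)
    vals = cw[iu]
    nz = vals != 0
    n = int(nz.sum())
    if n < 2:
        raise ValueError("need at least 2 nonzero upper-triangle entries")
    v = vals[nz]
    if np.all(v == v[0]):
        logger.warning("all nonzero CW entries equal; degenerate ranking maps all to 0.5")
        transformed = np.full(n, 0.5)
    else:
        ranks = sps.rankdata(v, method="average")
        transformed = 0.5 + 0.1 * sps.norm.ppf((ranks - 0.5) / n)
    out_vals = np.zeros_like(vals)
    out_vals[nz] = transformed
    out = np.zeros_like(cw)
    out[iu] = out_vals
    out = out + out.T
    return out


def node_metrics(connectome: ConnectomeSet) -> pd.DataFrame:
    """Row-sum nodal metrics: rFA from the FA matrix, CS from re-sampled CW."""
    if connectome.cw_resampled is None:
        raise ValueError("connectome has no cw_resampled; run resample_cw first")
    return pd.DataFrame({
        "roi_index": np.arange(connectome.n_rois),
        "rfa": connectome.fa_matrix.sum(axis=1),
        "cs": connectome.cw_resampled.sum(axis=1),
    })


def flip_hemispheres(
    connectome: ConnectomeSet,
    parcellation: Parcellation,
    lesion_side: str = "R",
) -> ConnectomeSet:
    """Mirror a right-lesion subject so the ipsilesional hemisphere is left.

    Rows/columns are permuted by the homotopic involution; subjects whose
    ``lesion_side`` is not ``"R"`` are returned unchanged.  Flipping twice
    restores the original matrices exactly.
    """
    if lesion_side != "R":
        return connectome
    perm = parcellation.homotopic_permutation()

    def p(m: np.ndarray | None) -> np.ndarray | None:
        return None if m is None else m[np.ix_(perm, perm)]

    out = replace(
        connectome,
        fa_matrix=p(connectome.fa_matrix),
        count_matrix=p(connectome.count_matrix),
        meanlen_matrix=p(connectome.meanlen_matrix),
        cw_matrix=p(connectome.cw_matrix),
        cw_resampled=p(connectome.cw_resampled),
        flipped=not connectome.flipped,
        meta={**connectome.meta, "hemisphere_flipped": not connectome.flipped},
    )
    return out


def group_subnetworks(
    parcellation: Parcellation,
    metrics: pd.DataFrame | None = None,
) -> dict[tuple[str, str], np.ndarray]:
    """Partition ROIs into the 12 (subnetwork x hemisphere) blocks.

    Returns a mapping ``(subnetwork, hemisphere) -> ROI index array``.  The
    blocks are checked to be disjoint and exhaustive.  If ``metrics`` is
    given it is only used to validate that every ROI index appears there.
    """
    blocks = {k: np.array(v) for k, v in parcellation.subnetwork_blocks().items()}
    covered = np.concatenate(list(blocks.values()))
    if len(covered) != len(set(covered.tolist())):
        raise ValueError("a ROI is assigned to more than one subnetwork block")
    if set(covered.tolist()) != set(range(len(parcellation))):
        missing = sorted(set(range(len(parcellation))) - set(covered.tolist()))
        raise ValueError(f"ROIs not assigned to any subnetwork block: {missing}")
    if metrics is not None:
        have = set(np.asarray(metrics["roi_index"]).tolist())
        if not set(covered.tolist()) <= have:
            raise ValueError("metric table does not cover every parcellation ROI")
    return blocks
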