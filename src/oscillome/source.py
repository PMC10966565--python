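"""Sensor-to-source mapping: minimum-norm inverse, orientation PCA, parcellation.

The inverse chain mirrors the standard distributed-source workflow:
a lead field ``G`` (sensors x 3*vertices, unconstrained dipole
orientations) is inverted with a regularized minimum-norm operator,
the three orientation components at each vertex are collapsed to one
time series by PCA, and vertex series are averaged (after sign
alignment) within parcellation regions grouped into nine functional
networks (DMN, DAN, SMN, VAN, FPN, VN, LN, SC, CB).

Real boundary-element head models are out of scope; the package works
with either a user-supplied gain matrix or the synthetic spherical
lead field from :func:`build_toy_leadfield`.
"""

from __future__ import annotations

from dataclasses import dataclass
from importlib import resources

import numpy as np
import pandas as pd

NETWORKS: tuple[str, ...] = (
    "DMN", "DAN", "SMN", "VAN", "FPN", "VN", "LN", "SC", "CB",
)


@dataclass
class ROITimeSeries:
    """Region x sample source-space signals with parcellation labels.

    The central object of the pipeline: band power and connectivity are
    both computed from it.
    """

    data: np.ndarray            # (n_regions, n_samples)
    fs: float
    region_names: list[str]
    network_labels: list[str]
    subject_id: str = ""
    group: str = ""

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data, dtype=float)
        if self.data.ndim != 2:
            raise ValueError("ROITimeSeries.data must be 2-D (regions x samples)")
        if self.data.shape[0] != len(self.region_names):
            raise ValueError(
                f"{self.data.shape[0]} rows but {len(self.region_names)} region names"
            )
        if len(self.region_names) != len(self.network_labels):
            raise ValueError("region_names and network_labels length mismatch")
        if np.isnan(self.data).any():
            raise ValueError("ROITimeSeries contains NaNs")

    @property
    def n_regions(self) -> int:
        return self.data.shape[0]

    @property
    def n_samples(self) -> int:
        return self.data.shape[1]

    @property
    def duration(self) -> float:
        return self.data.shape[1] / self.fs


@dataclass
class LeadField:
    """Gain matrix mapping dipole activity to sensors.

    ``matrix`` has shape (n_sensors, 3 * n_vertices): three consecutive
    columns per vertex, one per dipole orientation axis.
    """

    matrix: np.ndarray
    vertex_positions: np.ndarray | None = None
    sensor_positions: np.ndarray | None = None

    def __post_init__(self) -> None:
        self.matrix = np.asarray(self.matrix, dtype=float)
        if self.matrix.ndim != 2 or self.matrix.shape[1] % 3:
            raise ValueError("lead field must be (n_sensors, 3*n_vertices)")
        if not np.isfinite(self.matrix).all():
            raise ValueError("lead field contains non-finite entries")

    @property
    def n_sensors(self) -> int:
        return self.matrix.shape[0]

    @property
    def n_vertices(self) -> int:
        return self.matrix.shape[1] // 3


@dataclass
class Parcellation:
    """Region table: name, network membership, member vertex ids.

    Regions with fewer than ``min_vertices`` member vertices are
    excluded from analysis, and rows carrying a ``merge_into`` label
    (the thalamic subregions in the default table) are pooled into a
    single merged region before the size check.
    """

    table: pd.DataFrame  # columns: region, network, vertex_ids (list[int]), merge_into
    min_vertices: int = 5

    def __post_init__(self) -> None:
        required = {"region", "network", "vertex_ids"}
        if not required <= set(self.table.columns):
            raise ValueError(f"parcellation table needs columns {sorted(required)}")
        bad = set(self.table["network"]) - set(NETWORKS)
        if bad:
            raise ValueError(f"unknown networks {sorted(bad)}; expected {NETWORKS}")
        seen: set[int] = set()
        for vids in self.table["vertex_ids"]:
            s = set(vids)
            if seen & s:
                raise ValueError(
                    f"vertices assigned to two regions: {sorted(seen & s)[:5]}"
                )
            seen |= s

    @property
    def n_defined(self) -> int:
        return len(self.table)

    def preserved(self) -> pd.DataFrame:
        """Apply merge rules then the minimum-vertex exclusion.

        Returns a table of preserved regions (region, network,
        vertex_ids) in stable order.
        """
        rows: list[dict] = []
        merged: dict[str, dict] = {}
        for _, row in self.table.iterrows():
            target = row.get("merge_into") or None
            if isinstance(target, float) and np.isnan(target):
                target = None
            if target:
                slot = merged.setdefault(
                    target,
                    {"region": target, "network": row["network"], "vertex_ids": []},
                )
                slot["vertex_ids"] = list(slot["vertex_ids"]) + list(row["vertex_ids"])
                if slot not in rows:
                    rows.append(slot)
            else:
                rows.append(
                    {
                        "region": row["region"],
                        "network": row["network"],
                        "vertex_ids": list(row["vertex_ids"]),
                    }
                )
        # de-duplicate merged slots while keeping first-appearance order
        out, names = [], set()
        for r in rows:
            if r["region"] in names:
                continue
            names.add(r["region"])
            out.append(r)
        kept = [r for r in out if len(r["vertex_ids"]) >= self.min_vertices]
        return pd.DataFrame(kept, columns=["region", "network", "vertex_ids"])

    @property
    def n_preserved(self) -> int:
        return len(self.preserved())

    @property
    def n_vertices(self) -> int:
        return int(sum(len(v) for v in self.table["vertex_ids"]))


def load_parcellation_table(path=None, min_vertices: int = 5) -> Parcellation:
    """Load a parcellation from TSV (region, network, n_vertices, merge_into).

    Vertex ids are allocated contiguously in row order from the
    per-region counts.  Without ``path`` the bundled default table is
    used: 149 AAL3-style region rows whose merge + exclusion rules
    preserve 113 regions.  The bundled table is synthetic
    configuration — names and network assignments follow the AAL3 /
    seven-network conventions but the vertex allocations are toy
    values, not anatomy.
    """
    if path is None:
        with resources.files("oscillome.data").joinpath(
            "parcellation_149.tsv"
        ).open() as fh:
            raw = pd.read_csv(fh, sep="\t")
    else:
        raw = pd.read_csv(path, sep="\t")
    vertex_ids, cursor = [], 0
    for n in raw["n_vertices"].astype(int):
        vertex_ids.append(list(range(cursor, cursor + n)))
        cursor += n
    table = pd.DataFrame(
        {
            "region": raw["region"],
            "network": raw["network"],
            "vertex_ids": vertex_ids,
            "merge_into": raw.get("merge_into", pd.Series([None] * len(raw))),
        }
    )
    return Parcellation(table=table, min_vertices=min_vertices)


def build_toy_leadfield(
    n_sensors: int, n_vertices: int, seed: int | None = 0
) -> LeadField:
    """Synthetic spherical lead field with unconstrained orientations.

    Sensors sit on the unit sphere (Fibonacci lattice); vertices are
    scattered inside radius 0.8.  The gain of vertex ``v`` along axis
    ``e`` at sensor ``s`` is the dipole-like kernel
    ``e . (r_s - r_v) / |r_s - r_v|^3``, smooth in both positions and
    generically full rank.
    """
    if n_sensors < 2 or n_vertices < 1:
        raise ValueError("need n_sensors >= 2 and n_vertices >= 1")
    rng = np.random.default_rng(seed)
    # Fibonacci sphere for sensors
    i = np.arange(n_sensors)
    phi = np.pi * (3.0 - np.sqrt(5.0)) * i
    z = 1.0 - 2.0 * (i + 0.5) / n_sensors
    r = np.sqrt(1.0 - z**2)
    sensors = np.column_stack([r * np.cos(phi), r * np.sin(phi), z])
    # vertices uniform in the ball of radius 0.8
    v = rng.standard_normal((n_vertices, 3))
    v /= np.linalg.norm(v, axis=1, keepdims=True)
    radii = 0.8 * rng.uniform(0.2, 1.0, n_vertices) ** (1 / 3)
    vertices = v * radii[:, None]

    diff = sensors[:, None, :] - vertices[None, :, :]      # (S, V, 3)
    dist3 = np.linalg.norm(diff, axis=2) ** 3              # (S, V)
    gain = diff / dist3[:, :, None]                        # (S, V, 3)
    matrix = gain.reshape(n_sensors, 3 * n_vertices)
    return LeadField(matrix=matrix, vertex_positions=vertices, sensor_positions=sensors)


def minimum_norm_inverse(
    lf: LeadField,
    data: np.ndarray,
    lambda2: float = 1.0 / 9.0,
    noise_cov: np.ndarray | None = None,
) -> np.ndarray:
    """Regularized minimum-norm source estimate.

    Solves ``x = G' (G G' + lambda2 * s * C)^-1 y`` with ``G`` the lead
    field, ``C`` the sensor noise covariance (identity by default) and
    ``s = trace(G G') / trace(C)`` the gram scale, so that ``lambda2``
    is dimensionless and the default 1/9 carries its usual SNR=3
    meaning regardless of the lead field's units.

    Returns the (3*n_vertices, n_samples) orientation-resolved source
    estimate.
    """
    if lambda2 < 0:
        raise ValueError("lambda2 must be >= 0")
    G = lf.matrix
    data = np.asarray(data, dtype=float)
    if data.ndim == 1:
        data = data[None, :]
    if data.shape[0] != lf.n_sensors:
        raise ValueError(
            f"data has {data.shape[0]} channels but lead field expects {lf.n_sensors}"
        )
    C = np.eye(lf.n_sensors) if noise_cov is None else np.asarray(noise_cov, float)
    gg = G @ G.T
    scale = np.trace(gg) / np.trace(C)
    gram = gg + lambda2 * scale * C
    if lambda2 == 0 and np.linalg.matrix_rank(G) < lf.n_sensors:
        raise np.linalg.LinAlgError(
            "lead field is rank-deficient and lambda2=0; use lambda2 > 0"
        )
    try:
        kernel = np.linalg.solve(gram, data)
    except np.linalg.LinAlgError as err:
        raise np.linalg.LinAlgError(
            f"singular sensor gram matrix ({err}); use lambda2 > 0"
        ) from err
    return G.T @ kernel


def orientation_pca(vertex_xyz: np.ndarray) -> np.ndarray:
    """Collapse a 3 x n_samples dipole series to its first PC score series.

    Source series are zero-mean by construction, so no mean removal is
    applied; the first right singular vector's score series therefore
    carries at least as much power as any single axis.  All-zero input
    returns the zero series.
    """
    x = np.asarray(vertex_xyz, dtype=float)
    if x.shape[0] != 3 or x.ndim != 2:
        raise ValueError("expected a 3 x n_samples array")
    if x.shape[1] < 2:
        raise ValueError("need at least 2 samples")
    if not x.any():
        return np.zeros(x.shape[1])
    u, s, vt = np.linalg.svd(x, full_matrices=False)
    return s[0] * vt[0]


def _sign_align(series: np.ndarray) -> np.ndarray:
    """Flip rows so each correlates non-negatively with the first PC."""
    if series.shape[0] == 1:
        return series
    u, s, vt = np.linalg.svd(series, full_matrices=False)
    pc = vt[0]
    signs = np.sign(series @ pc)
    signs[signs == 0] = 1.0
    return series * signs[:, None]


def parcellate(
    vertex_series: np.ndarray,
    parcellation: Parcellation,
    fs: float,
    subject_id: str = "",
    group: str = "",
) -> ROITimeSeries:
    """Average sign-aligned member-vertex series into region series.

    ``vertex_series`` is (n_vertices, n_samples), one orientation-
    collapsed series per vertex.  Each vertex is flipped to correlate
    positively with its region's first principal component before
    averaging, so the output is invariant to arbitrary per-vertex sign
    conventions of the inverse solution.
    """
    vertex_series = np.asarray(vertex_series, dtype=float)
    kept = parcellation.preserved()
    data = np.empty((len(kept), vertex_series.shape[1]))
    for i, (_, row) in enumerate(kept.iterrows()):
        members = vertex_series[np.asarray(row["vertex_ids"], dtype=int)]
        data[i] = _sign_align(members).mean(axis=0)
    return ROITimeSeries(
        data=data,
        fs=fs,
        region_names=list(kept["region"]),
        network_labels=list(kept["network"]),
        subject_id=subject_id,
        group=group,
    )


def collapse_orientations(source_estimate: np.ndarray) -> np.ndarray:
    """Apply :func:`orientation_pca` to every vertex of a 3*V x T estimate."""
    est = np.asarray(source_estimate, dtype=float)
    if est.shape[0] % 3:
        raise ValueError("first dimension must be 3 * n_vertices")
    n_vertices = est.shape[0] // 3
    out = np.empty((n_vertices, est.shape[1]))
    for v in range(n_vertices):
        out[v] = orientation_pca(est[3 * v : 3 * v + 3])
    return out
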