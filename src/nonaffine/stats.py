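"""Ensemble aggregation of chi: time profiles, susceptibility, correlation maps.

Per-site statistics use the population (1/T) variance convention, matching
ensemble-average notation.  The NAP susceptibility <(chi - <chi>)^2> flags
ligand hotspots in the apo ensemble; the same-time residue-residue
covariance <(chi_i - <chi_i>)(chi_j - <chi_j>)> flags candidate allosteric
pairs once trivially-correlated near neighbors are filtered out.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.spatial.distance import cdist

from .core import build_projection, chi_series
from .io import ConformationEnsemble, ReferenceStructure
from .neighborhoods import Neighborhood
from .spectral import correlator, pcp_spectrum

DEFAULT_THRESHOLD_FRACTION = 0.04   # the 4%-of-maximum covariance cut
DEFAULT_MIN_SEQ_SEP = 10            # residues
DEFAULT_MIN_DISTANCE = 12.0         # Angstrom, reference C-alpha (or centroid)


@dataclass
class NapTimeSeries:
    """Per-frame chi for one site (atom, residue, or labelled selection)."""

    site: object
    chi_t: np.ndarray
    frame_times: np.ndarray | None = None

    def __post_init__(self):
        self.chi_t = np.asarray(self.chi_t, dtype=float)
        if np.any(self.chi_t < 0):
            raise ValueError("chi must be non-negative")


@dataclass
class NapStatistics:
    """Per-site mean chi, susceptibility and spectral gap."""

    sites: np.ndarray
    mean_chi: np.ndarray
    susceptibility: np.ndarray
    gap: np.ndarray
    n_frames: int

    def as_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "site": self.sites,
                "mean_chi": self.mean_chi,
                "susceptibility": self.susceptibility,
                "gap": self.gap,
            }
        )


@dataclass
class NapCorrelationMap:
    """Same-time covariance of residue-level chi series."""

    residue_ids: np.ndarray
    matrix: np.ndarray
    threshold_fraction: float = DEFAULT_THRESHOLD_FRACTION
    pairs: pd.DataFrame | None = field(default=None)


def chi_timeseries(
    ref: ReferenceStructure,
    ensemble: ConformationEnsemble,
    site_indices,
    neighborhoods: dict,
    label: str = "selection",
    per_atom: bool = False,
) -> NapTimeSeries:
    """chi averaged per frame over a selection's atoms with valid neighborhoods."""
    series = []
    for idx in site_indices:
        nb = neighborhoods.get(int(idx))
        if nb is not None:
            series.append(chi_series(ref, ensemble, nb, per_atom=per_atom))
    if not series:
        raise ValueError(
            f"no atom of selection {label!r} has a valid neighborhood"
        )
    return NapTimeSeries(
        site=label,
        chi_t=np.mean(series, axis=0),
        frame_times=ensemble.frame_times,
    )


def site_statistics(
    series: dict,
    gaps: dict | None = None,
) -> NapStatistics:
    """Mean and population-variance susceptibility for per-site chi series.

    ``series`` maps site id -> per-frame chi array; ``gaps`` optionally maps
    site id -> spectral gap Gamma (NaN marks sites without a spectrum).
    """
    sites = np.array(list(series.keys()), dtype=object)
    if len(sites) == 0:
        raise ValueError("no sites given")
    lengths = {len(np.asarray(s)) for s in series.values()}
    if len(lengths) != 1:
        raise ValueError("all chi series must have the same length")
    T = lengths.pop()
    if T < 2:
        raise ValueError("need at least 2 frames for susceptibility")
    chi = np.array([np.asarray(series[s], dtype=float) for s in sites])
    mean = chi.mean(axis=1)
    susceptibility = chi.var(axis=1)  # population convention, ddof=0
    gap = np.array([gaps.get(s, np.nan) if gaps else np.nan for s in sites], dtype=float)
    return NapStatistics(
        sites=sites, mean_chi=mean, susceptibility=susceptibility, gap=gap, n_frames=T
    )


def atom_chi_series(
    ref: ReferenceStructure,
    ensemble: ConformationEnsemble,
    neighborhoods: dict,
    per_atom: bool = False,
) -> dict:
    """Per-atom chi series for every valid neighborhood (atom index -> (T,) array)."""
    return {
        idx: chi_series(ref, ensemble, nb, per_atom=per_atom)
        for idx, nb in neighborhoods.items()
    }


def residue_chi_series(
    ref: ReferenceStructure,
    atom_series: dict,
) -> dict:
    """Residue-level chi: mean over each residue's heavy atoms with valid series."""
    residue_series: dict[int, list] = {}
    heavy = ref.heavy_mask
    for idx, series in atom_series.items():
        if not heavy[idx]:
            continue
        rid = int(ref.residue_id[idx])
        residue_series.setdefault(rid, []).append(series)
    return {rid: np.mean(stack, axis=0) for rid, stack in sorted(residue_series.items())}


def site_spectra(
    ref: ReferenceStructure,
    ensemble: ConformationEnsemble,
    neighborhoods: dict,
    mean_subtract: bool = False,
) -> dict:
    """PCP spectrum per site (atom index -> NapSpectrum)."""
    from .core import displacement_matrix

    spectra = {}
    for idx, nb in neighborhoods.items():
        proj = build_projection(nb)
        corr = correlator(
            displacement_matrix(ref, ensemble, nb), mean_subtract=mean_subtract
        )
        spectra[idx] = pcp_spectrum(proj, corr)
    return spectra


def correlation_map(
    residue_series: dict,
    threshold_fraction: float = DEFAULT_THRESHOLD_FRACTION,
) -> NapCorrelationMap:
    """Same-time covariance matrix over residue-level chi series.

    The diagonal is, by construction, the per-residue susceptibility.
    """
    rids = np.array(sorted(residue_series.keys()), dtype=int)
    if len(rids) < 2:
        raise ValueError("need at least 2 residues for a correlation map")
    chi = np.array([np.asarray(residue_series[r], dtype=float) for r in rids])
    T = chi.shape[1]
    if T < 2:
        raise ValueError("need at least 2 frames for a correlation map")
    centered = chi - chi.mean(axis=1, keepdims=True)
    matrix = centered @ centered.T / T
    matrix = 0.5 * (matrix + matrix.T)
    # diagonal recomputed with the same estimator site_statistics uses, so
    # map(i,i) equals the per-residue susceptibility bit-exactly
    matrix[np.diag_indices_from(matrix)] = chi.var(axis=1)
    return NapCorrelationMap(
        residue_ids=rids, matrix=matrix, threshold_fraction=threshold_fraction
    )


def _residue_anchor_positions(ref: ReferenceStructure, residue_ids: np.ndarray) -> np.ndarray:
    """C-alpha position per residue, or heavy-atom centroid where CA is absent."""
    anchors = np.empty((len(residue_ids), 3))
    for k, rid in enumerate(residue_ids):
        in_res = ref.residue_id == rid
        ca = in_res & (ref.atom_name == "CA")
        if ca.any():
            anchors[k] = ref.positions[ca][0]
        else:
            heavy = in_res & ref.heavy_mask
            pick = heavy if heavy.any() else in_res
            anchors[k] = ref.positions[pick].mean(axis=0)
    return anchors


def threshold_pairs(
    cmap: NapCorrelationMap,
    ref: ReferenceStructure,
    fraction: float | None = None,
    min_seq_sep: int = DEFAULT_MIN_SEQ_SEP,
    min_distance: float = DEFAULT_MIN_DISTANCE,
) -> pd.DataFrame:
    """Supra-threshold, spatially distant residue pairs ranked by covariance.

    Pairs with covariance above ``fraction`` of the maximum off-diagonal
    entry, sequence separation >= ``min_seq_sep`` residues and reference
    anchor (C-alpha or centroid) distance >= ``min_distance`` A.  Adjacent
    residues are trivially correlated through direct contact, hence the two
    distance filters.
    """
    if fraction is None:
        fraction = cmap.threshold_fraction
    if not 0 < fraction <= 1:
        raise ValueError(f"fraction must be in (0, 1], got {fraction}")
    rids = cmap.residue_ids
    M = cmap.matrix
    off = M[~np.eye(len(rids), dtype=bool)]
    if len(off) == 0 or np.max(off) <= 0:
        threshold = np.inf
    else:
        threshold = fraction * np.max(off)
    anchors = _residue_anchor_positions(ref, rids)
    dist = cdist(anchors, anchors)
    rows = []
    for a in range(len(rids)):
        for b in range(a + 1, len(rids)):
            if abs(int(rids[b]) - int(rids[a])) < min_seq_sep:
                continue
            if dist[a, b] < min_distance:
                continue
            if M[a, b] >= threshold:
                rows.append(
                    {
                        "residue_i": int(rids[a]),
                        "residue_j": int(rids[b]),
                        "covariance": float(M[a, b]),
                        "distance": float(dist[a, b]),
                        "seq_separation": abs(int(rids[b]) - int(rids[a])),
                    }
                )
    pairs = pd.DataFrame(
        rows, columns=["residue_i", "residue_j", "covariance", "distance", "seq_separation"]
    )
    if len(pairs):
        pairs = pairs.sort_values("covariance", ascending=False, ignore_index=True)
    cmap.pairs = pairs
    return pairs


def interhelix_distance(frame: np.ndarray, sel_a, sel_b) -> float:
    """Mean over all cross pairs of Euclidean distances between two selections."""
    sel_a = np.asarray(sel_a, dtype=int)
    sel_b = np.asarray(sel_b, dtype=int)
    if sel_a.size == 0 or sel_b.size == 0:
        raise ValueError("both selections must be non-empty")
    frame = np.asarray(frame, dtype=float)
    return float(cdist(frame[sel_a], frame[sel_b]).mean())


def interhelix_distance_series(
    ensemble: ConformationEnsemble, sel_a, sel_b
) -> np.ndarray:
    """Mean all-pairs distance per frame."""
    return np.array(
        [interhelix_distance(f, sel_a, sel_b) for f in ensemble.frames]
    )


def hotspot_scale(susceptibility: np.ndarray) -> np.ndarray:
    """Min-max rescaling of susceptibilities to the 0 (blue) - 100 (red) scale.

    NaN entries (excluded sites) stay NaN; an all-equal input maps to all
    zeros by convention.
    """
    s = np.asarray(susceptibility, dtype=float)
    valid = np.isfinite(s)
    out = np.full_like(s, np.nan)
    if not valid.any():
        return out
    lo, hi = s[valid].min(), s[valid].max()
    if hi == lo:
        out[valid] = 0.0
    else:
        out[valid] = 100.0 * (s[valid] - lo) / (hi - lo)
    return out
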