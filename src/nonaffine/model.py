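"""Model/Results interface tying the analysis together.

:class:`NonAffineModel` is constructed from a reference structure and a
conformational ensemble; :meth:`NonAffineModel.fit` computes per-site chi
series, susceptibilities and (on request) PCP spectra and returns a
:class:`NonAffineResults` carrying the estimates, residue aggregates,
correlation map and a ``summary()`` table.  Reports and mode export hang
off the results object.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from . import io, neighborhoods as nbh, stats
from .core import build_projection, displacement_matrix
from .io import ConformationEnsemble, ReferenceStructure
from .spectral import NapSpectrum, correlator, dominant_mode, mp_fit, pcp_spectrum


class NonAffineModel:
    """Non-affine displacement model of an ensemble about a reference.

    Parameters
    ----------
    reference : ReferenceStructure
        Fixed positions R_i; typically the crystal/native structure.
    ensemble : ConformationEnsemble
        Frames r_i(t) in the reference atom order.
    sites : str or sequence of int, optional
        Atoms to analyse; a selection query (default ``"heavy"``) or
        explicit 0-based indices.
    radius : float, optional
        Neighborhood radius in Angstrom.  If omitted it is calibrated so
        the median heavy-atom neighborhood holds ``target_n`` atoms.
    target_n : (int, int)
        Calibration target for the neighborhood size (default 50-100).
    heavy_only : bool
        Restrict neighborhood members to heavy atoms (default True).
    min_size : int
        Minimum members per neighborhood; smaller sites are excluded and
        reported in ``results.excluded_sites``.
    mean_subtract : bool
        Subtract the mean Delta when building correlators (for drifted
        ensembles); default False keeps the trace identity exact.
    per_atom : bool
        Report chi divided by n_omega instead of the raw sum.
    """

    def __init__(
        self,
        reference: ReferenceStructure,
        ensemble: ConformationEnsemble,
        sites="heavy",
        radius: float | None = None,
        target_n=nbh.DEFAULT_TARGET_N,
        heavy_only: bool = True,
        min_size: int = nbh.DEFAULT_MIN_SIZE,
        mean_subtract: bool = False,
        per_atom: bool = False,
    ):
        if ensemble.n_atoms != reference.n_atoms:
            raise ValueError(
                f"atom count mismatch: reference has {reference.n_atoms}, "
                f"ensemble has {ensemble.n_atoms}"
            )
        self.reference = reference
        self.ensemble = ensemble
        if isinstance(sites, str):
            self.site_indices = io.select_atoms(reference, sites)
            self.site_query = sites
        else:
            self.site_indices = np.asarray(sorted(set(int(s) for s in sites)), dtype=int)
            self.site_query = None
        self.radius = radius
        self.target_n = target_n
        self.heavy_only = heavy_only
        self.min_size = min_size
        self.mean_subtract = mean_subtract
        self.per_atom = per_atom

    @classmethod
    def from_files(
        cls, topology, trajectory=None, model_index: int = 0, **kwargs
    ) -> "NonAffineModel":
        """Build a model straight from a reference PDB and a trajectory file."""
        reference = io.load_reference(topology, model_index=model_index)
        ensemble = io.load_ensemble(topology, trajectory)
        return cls(reference, ensemble, **kwargs)

    def fit(self, spectrum_sites=None) -> "NonAffineResults":
        """Compute chi statistics for every analysed site.

        ``spectrum_sites`` selects sites whose PCP spectrum (gap, modes) is
        computed eagerly: ``None`` (lazily on demand), ``"all"``, or a list
        of atom indices.  Spectra for other sites remain available through
        :meth:`NonAffineResults.spectrum`.
        """
        radius = self.radius
        if radius is None:
            radius = nbh.calibrate_radius(
                self.reference, self.target_n, heavy_only=self.heavy_only
            )
        neighborhood_map, failures = nbh.build_neighborhoods(
            self.reference,
            self.site_indices,
            radius,
            heavy_only=self.heavy_only,
            min_size=self.min_size,
        )
        if not neighborhood_map:
            raise ValueError(
                f"all {len(self.site_indices)} requested sites have degenerate "
                "neighborhoods; increase the radius or lower min_size"
            )
        atom_series = stats.atom_chi_series(
            self.reference, self.ensemble, neighborhood_map, per_atom=self.per_atom
        )
        results = NonAffineResults(
            model=self,
            radius=radius,
            neighborhoods=neighborhood_map,
            excluded_sites=failures,
            atom_series=atom_series,
        )
        if spectrum_sites is not None:
            wanted = (
                list(neighborhood_map) if spectrum_sites == "all" else spectrum_sites
            )
            for site in wanted:
                results.spectrum(int(site))
        return results


class NonAffineResults:
    """Fitted NAP statistics: per-atom chi, spectra, residue aggregates."""

    def __init__(self, model, radius, neighborhoods, excluded_sites, atom_series):
        self.model = model
        self.reference = model.reference
        self.ensemble = model.ensemble
        self.radius = radius
        self.neighborhoods = neighborhoods
        self.excluded_sites = excluded_sites
        self.atom_series = atom_series
        self.n_frames = model.ensemble.n_frames
        self._spectra: dict[int, NapSpectrum] = {}
        self._residue_series = None
        self._cmap = None

    # -- spectra ---------------------------------------------------------

    def spectrum(self, site: int) -> NapSpectrum:
        """PCP spectrum of one site, computed once and cached."""
        site = int(site)
        if site not in self._spectra:
            nb = self.neighborhoods.get(site)
            if nb is None:
                raise KeyError(f"site {site} has no valid neighborhood")
            proj = build_projection(nb)
            corr = correlator(
                displacement_matrix(self.reference, self.ensemble, nb),
                mean_subtract=self.model.mean_subtract,
            )
            self._spectra[site] = pcp_spectrum(proj, corr)
        return self._spectra[site]

    def gap(self, site: int) -> float:
        return self.spectrum(site).gap

    def dominant_mode(self, site: int) -> np.ndarray:
        """Dominant non-affine displacement field of a site, (n_omega, 3)."""
        return dominant_mode(self.spectrum(site), self.neighborhoods[int(site)])

    def mode_displacement_field(self, site: int) -> np.ndarray:
        """Dominant mode embedded as an (N, 3) per-atom field (zero elsewhere)."""
        nb = self.neighborhoods[int(site)]
        field = np.zeros_like(self.reference.positions)
        field[nb.member_indices] = self.dominant_mode(site)
        return field

    def write_mode_pdb(self, path, site: int, scale: float = 10.0) -> None:
        """Export the dominant mode of a site as a 2-model PDB for animation."""
        io.write_mode_pdb(
            path, self.reference, self.mode_displacement_field(site), scale=scale
        )

    def mp_fit(self, site: int):
        """Moment-matched Marchenko-Pastur fit to a site's non-zero spectrum."""
        return mp_fit(self.spectrum(site), self.n_frames)

    # -- per-atom and per-residue tables ---------------------------------

    def site_statistics(self, with_gaps: bool = False) -> stats.NapStatistics:
        gaps = {s: self.spectrum(s).gap for s in self.atom_series} if with_gaps else (
            {s: spec.gap for s, spec in self._spectra.items()}
        )
        return stats.site_statistics(self.atom_series, gaps)

    def site_table(self, with_gaps: bool = False) -> pd.DataFrame:
        table = self.site_statistics(with_gaps).as_frame()
        table = table.rename(columns={"site": "atom_index"})
        idx = table["atom_index"].to_numpy(dtype=int)
        table.insert(1, "residue_id", self.reference.residue_id[idx])
        table.insert(1, "atom_name", self.reference.atom_name[idx])
        return table

    def residue_series(self) -> dict:
        if self._residue_series is None:
            self._residue_series = stats.residue_chi_series(
                self.reference, self.atom_series
            )
        return self._residue_series

    def residue_table(self) -> pd.DataFrame:
        """Per-residue mean chi, susceptibility and hotspot scale (0-100)."""
        series = self.residue_series()
        rids = np.array(sorted(series.keys()), dtype=int)
        chi = np.array([series[r] for r in rids])
        mean = chi.mean(axis=1)
        susceptibility = chi.var(axis=1)
        chains = []
        for rid in rids:
            mask = self.reference.residue_id == rid
            chains.append(self.reference.chain_id[mask][0])
        return pd.DataFrame(
            {
                "residue_id": rids,
                "chain": chains,
                "mean_chi": mean,
                "susceptibility": susceptibility,
                "hotspot_scale": stats.hotspot_scale(susceptibility),
            }
        )

    def hotspot_bfactors(self) -> np.ndarray:
        """Per-atom hotspot values (residue susceptibility min-max scaled 0-100)."""
        table = self.residue_table()
        scale = dict(zip(table["residue_id"], table["hotspot_scale"]))
        return np.array(
            [scale.get(int(r), 0.0) for r in self.reference.residue_id], dtype=float
        )

    def write_hotspot_pdb(self, path) -> None:
        """Reference PDB with the 0-100 hotspot scale in the B-factor column."""
        io.write_bfactor_pdb(path, self.reference, self.hotspot_bfactors())

    # -- correlation map and pairs ---------------------------------------

    def correlation_map(self, threshold_fraction=stats.DEFAULT_THRESHOLD_FRACTION):
        if self._cmap is None or self._cmap.threshold_fraction != threshold_fraction:
            self._cmap = stats.correlation_map(
                self.residue_series(), threshold_fraction=threshold_fraction
            )
        return self._cmap

    def threshold_pairs(
        self,
        fraction: float = stats.DEFAULT_THRESHOLD_FRACTION,
        min_seq_sep: int = stats.DEFAULT_MIN_SEQ_SEP,
        min_distance: float = stats.DEFAULT_MIN_DISTANCE,
    ) -> pd.DataFrame:
        """Ranked supra-threshold, spatially distant residue pairs."""
        return stats.threshold_pairs(
            self.correlation_map(fraction),
            self.reference,
            fraction=fraction,
            min_seq_sep=min_seq_sep,
            min_distance=min_distance,
        )

    # -- time series ------------------------------------------------------

    def chi_timeseries(self, selection, label=None) -> stats.NapTimeSeries:
        """chi averaged per frame over a selection (query string or indices)."""
        if isinstance(selection, str):
            indices = io.select_atoms(self.reference, selection)
            label = label or selection
        else:
            indices = np.asarray(selection, dtype=int)
            label = label or "selection"
        return stats.chi_timeseries(
            self.reference,
            self.ensemble,
            indices,
            self.neighborhoods,
            label=label,
            per_atom=self.model.per_atom,
        )

    def distance_series(self, selection_a, selection_b) -> np.ndarray:
        """Mean all-cross-pair distance between two selections, per frame."""
        sel_a = (
            io.select_atoms(self.reference, selection_a)
            if isinstance(selection_a, str)
            else np.asarray(selection_a, dtype=int)
        )
        sel_b = (
            io.select_atoms(self.reference, selection_b)
            if isinstance(selection_b, str)
            else np.asarray(selection_b, dtype=int)
        )
        return stats.interhelix_distance_series(self.ensemble, sel_a, sel_b)

    # -- summary ----------------------------------------------------------

    def summary(self, top: int = 5) -> str:
        """Plain-text summary of the fitted NAP statistics."""
        table = self.residue_table()
        hot = table.sort_values("susceptibility", ascending=False).head(top)
        lines = [
            "Non-Affine Parameter analysis",
            "=" * 64,
            f"atoms (reference):        {self.reference.n_atoms}",
            f"frames:                   {self.n_frames}",
            f"neighborhood radius:      {self.radius:.2f} A"
            + ("" if self.model.radius is not None else "  (calibrated)"),
            f"analysed sites:           {len(self.atom_series)}",
            f"excluded sites:           {len(self.excluded_sites)}",
            f"median neighborhood size: "
            f"{int(np.median([nb.n_members for nb in self.neighborhoods.values()]))}",
            f"chi convention:           "
            + ("per-atom (chi / n_omega)" if self.model.per_atom else "neighborhood sum"),
            "",
            f"top {len(hot)} residues by NAP susceptibility "
            "(candidate ligand hotspots):",
            hot.to_string(
                index=False,
                float_format=lambda v: f"{v:.4g}",
                columns=["residue_id", "chain", "mean_chi", "susceptibility", "hotspot_scale"],
            ),
        ]
        if self._spectra:
            gaps = {s: spec.gap for s, spec in self._spectra.items()}
            best = max(gaps, key=gaps.get)
            lines += [
                "",
                f"spectra computed for {len(gaps)} site(s); "
                f"largest gap {gaps[best]:.3f} at atom {best}",
            ]
        return "\n".join(lines)

    def __repr__(self):
        return (
            f"<NonAffineResults: {len(self.atom_series)} sites, "
            f"{self.n_frames} frames, radius {self.radius:.2f} A>"
        )
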