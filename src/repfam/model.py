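"""Model/Results facade over the discovery pipeline.

``RepeatDiscovery`` is constructed from a genome and a configuration;
``fit()`` runs the complete procedure - iterative profile refinement,
family acceptance and masking, both-strand search with the accepted profile
and its inversion, per-family FDR calibration against a shuffled genome,
and cross-family overlap resolution - and returns a
``RepeatDiscoveryResults`` object carrying the families, the final hit
table, the FDR tables and a summary.
"""

from __future__ import annotations

import json
import logging
from pathlib import Path

import numpy as np
import pandas as pd

from . import __version__
from .discovery import RepeatFamily, discover_families
from .genome import (GenomeIndex, hits_to_frame, load_genome,
                     write_bed, write_repeat_table)
from .pwm import PWMConfig, save_pwm
from .scan import local_maxima
from .simulate import PlantedTruth, evaluate_recovery
from .stats import ConsensusProfile, build_count_matrix, length_histogram
from .strands import (DEFAULT_Z0_GRID, RepeatHit, _hits_from_profile,
                      calibrate_fdr, maxima_counts, resolve_overlaps,
                      search_family)

log = logging.getLogger(__name__)


class RepeatDiscovery:
    """De novo dispersed-repeat family discovery on a genome.

    Parameters
    ----------
    genome
        A :class:`GenomeIndex` (see :meth:`from_fasta` to read one).
    config
        A :class:`PWMConfig`; keyword overrides may be passed instead.
    """

    def __init__(self, genome: GenomeIndex, config: PWMConfig | None = None,
                 **overrides):
        if config is None:
            config = PWMConfig(**overrides)
        elif overrides:
            raise TypeError("pass either config or keyword overrides, not both")
        self.genome = genome
        self.config = config

    @classmethod
    def from_fasta(cls, path, config: PWMConfig | None = None,
                   **overrides) -> "RepeatDiscovery":
        return cls(load_genome(path), config=config, **overrides)

    def fit(self, seed: int | None = None, max_families: int | None = None,
            search_strands: bool = True) -> "RepeatDiscoveryResults":
        """Run discovery and (optionally) the calibrated both-strand search."""
        from .genome import shuffle_genome

        cfg = self.config
        if seed is None:
            seed = cfg.seed
        shuffled = shuffle_genome(self.genome, seed=(seed * 1_000_003 + 7)
                                  % (2**31))
        families = discover_families(self.genome, cfg, seed=seed,
                                     shuffled=shuffled,
                                     max_families=max_families)
        hits: list[RepeatHit] = []
        if search_strands:
            for fam in families:
                fam_hits = self._search_and_calibrate(fam, shuffled)
                hits.extend(fam_hits)
            hits = resolve_overlaps(hits)
        return RepeatDiscoveryResults(self, families, hits, seed=seed)

    def _search_and_calibrate(self, fam: RepeatFamily,
                              shuffled: GenomeIndex) -> list[RepeatHit]:
        """Both-strand search plus FDR-based per-family Z0 selection."""
        cfg = self.config
        profiles = search_family(self.genome, shuffled, fam.pwm, cfg,
                                 fam.family, Z0=0.0, count_only=True)
        grid = np.asarray(DEFAULT_Z0_GRID)
        TP = np.zeros(len(grid), dtype=np.int64)
        FP = np.zeros(len(grid), dtype=np.int64)
        for label in ("direct", "inverted"):
            real, rand, _ = profiles[label]
            TP += maxima_counts(real, grid, cfg.maxima_halfwidth)
            FP += maxima_counts(rand, grid, cfg.maxima_halfwidth)
        table = calibrate_fdr(TP, FP, grid, cfg.fdr_max)
        if not table.attained:
            log.warning("family %d: no grid Z0 met FDR <= %.1f%%; using %.1f",
                        fam.family, 100 * cfg.fdr_max, table.Z0_selected)
        fam.Z0_family = table.Z0_selected
        fam.fdr_table = table
        hits: list[RepeatHit] = []
        from .pwm import invert_pwm

        for label, strand in (("direct", "+"), ("inverted", "-")):
            real, _, _ = profiles[label]
            maxima = local_maxima(real, fam.Z0_family, cfg.maxima_halfwidth)
            mat = fam.pwm if label == "direct" else invert_pwm(fam.pwm)
            hits.extend(_hits_from_profile(self.genome, mat, cfg, real,
                                           maxima, fam.family, strand, label))
        return hits


class RepeatDiscoveryResults:
    """Fitted families, final hit set, and per-family diagnostics."""

    def __init__(self, model: RepeatDiscovery, families: list[RepeatFamily],
                 hits: list[RepeatHit], seed: int):
        self.model = model
        self.families = families
        self.hits = hits
        self.seed = seed

    @property
    def n_families(self) -> int:
        return len(self.families)

    def hits_frame(self) -> pd.DataFrame:
        return hits_to_frame(self.hits)

    def summary(self) -> pd.DataFrame:
        """One row per accepted family."""
        rows = []
        for fam in self.families:
            n_plus = sum(1 for h in self.hits
                         if h.family == fam.family and h.strand == "+")
            n_minus = sum(1 for h in self.hits
                          if h.family == fam.family and h.strand == "-")
            fdr = None
            if fam.fdr_table is not None:
                sel = np.nonzero(fam.fdr_table.grid == fam.Z0_family)[0]
                fdr = float(fam.fdr_table.FDR[sel[0]]) if len(sel) else None
            rows.append({"family": fam.family, "N_max": fam.N_max,
                         "i_max": fam.i_max, "matrix": fam.matrix_index,
                         "hits_plus": n_plus, "hits_minus": n_minus,
                         "Z0": fam.Z0_family, "FDR": fdr})
        return pd.DataFrame(rows)

    def _family(self, family_id: int) -> RepeatFamily:
        for fam in self.families:
            if fam.family == family_id:
                return fam
        raise KeyError(f"no family with id {family_id}")

    def consensus(self, family_id: int, use_final_hits: bool = True
                  ) -> ConsensusProfile:
        """Consensus profile from re-aligned members.

        With ``use_final_hits`` the calibrated both-strand hit set is used
        (when available); otherwise the one-strand discovery members.
        """
        fam = self._family(family_id)
        if use_final_hits and self.hits:
            final = [h for h in self.hits if h.family == family_id]
            if final:
                proxy = RepeatFamily(family=fam.family, pwm=fam.pwm,
                                     N_max=fam.N_max, i_max=fam.i_max,
                                     matrix_index=fam.matrix_index,
                                     hits=final)
                return build_count_matrix(proxy, self.model.genome,
                                          self.model.config)
        return build_count_matrix(fam, self.model.genome, self.model.config)

    def evaluate(self, truth: PlantedTruth, match_fraction: float = 0.5):
        """Score the final hits (or, without a strand search, the discovery
        members) against a planted truth."""
        hits = self.hits or [h for fam in self.families for h in fam.hits]
        return evaluate_recovery(hits, truth, match_fraction)

    def length_summary(self):
        hits = self.hits or [h for fam in self.families for h in fam.hits]
        return length_histogram(hits)

    def plot_length_histogram(self, ax=None, bins: int = 20):
        import matplotlib.pyplot as plt

        hits = self.hits or [h for fam in self.families for h in fam.hits]
        lengths = [h.end - h.start + 1 for h in hits]
        if ax is None:
            _, ax = plt.subplots()
        ax.hist(lengths, bins=bins)
        ax.set_xlabel("repeat length (bp)")
        ax.set_ylabel("count")
        return ax

    def save(self, outdir) -> None:
        """Write hit tables (CSV + BED, per strand), FDR tables, profiles,
        consensus files and the run manifest."""
        out = Path(outdir)
        out.mkdir(parents=True, exist_ok=True)
        hits = self.hits or [h for fam in self.families for h in fam.hits]
        direct = [h for h in hits if h.strand == "+"]
        inverted = [h for h in hits if h.strand == "-"]
        write_repeat_table(direct, out / "repeats_dir.csv")
        write_repeat_table(inverted, out / "repeats_inv.csv")
        write_bed(hits, out / "repeats.bed")
        for fam in self.families:
            save_pwm(fam.pwm, out / f"family{fam.family}.pwm",
                     meta={"family": fam.family, "N_max": fam.N_max,
                           "i_max": fam.i_max})
            if fam.fdr_table is not None:
                fam.fdr_table.to_frame().to_csv(
                    out / f"family{fam.family}_fdr.tsv", sep="\t", index=False)
        self.summary().to_csv(out / "summary.csv", index=False)
        manifest = {"version": __version__, "seed": self.seed,
                    "config": self.model.config.to_dict(),
                    "n_families": self.n_families,
                    "families": [{"family": f.family, "N_max": f.N_max,
                                  "i_max": f.i_max, "Z0": f.Z0_family,
                                  "n_z_series": f.n_z_series}
                                 for f in self.families]}
        with open(out / "manifest.json", "w") as fh:
            json.dump(manifest, fh, indent=2)
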