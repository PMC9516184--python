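"""End-to-end orchestration: simulate? -> merge -> compare -> annotate ->
integrate -> motifs, with a machine-readable manifest.

Every stage writes plain-text outputs under the run directory and
contributes counts to ``manifest.json``. The manifest records package
version, parameters, and SHA-256 checksums of inputs and outputs (no
timestamps or absolute paths), so re-running the same configuration on
the same inputs reproduces it byte for byte.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional

import pandas as pd
import yaml

from . import __version__
from .annotate import associate_peaks, tss_distance_histogram
from .condition import (
    apply_presence_flags,
    classify_presence,
    flag_control_overlap,
)
from .consensus import consensus_summary, merge_replicates
from .integrate import call_targets, classify_regulation, overlap_test
from .io import (
    CONDITIONS,
    CONTROL_CU,
    LOW_CU,
    TAGGED,
    UNTAGGED_CONTROL,
    read_de_table,
    read_gff3_genes,
    read_peaks,
    write_bed,
)
from .motif import (
    center_distance_density,
    normalized_position_profile,
    sites_per_peak,
)
from .simulate import CONTRAST_BY_CONDITION, SimConfig, simulate

logger = logging.getLogger(__name__)


class StageError(RuntimeError):
    """A pipeline stage failed; names the stage and the cause."""

    def __init__(self, stage: str, cause: BaseException):
        self.stage = stage
        super().__init__(f"stage {stage!r} failed: {cause}")


@dataclass
class RunConfig:
    """Flat run configuration; defaults are the reference parameters
    (80% merge fraction, support >= 2 of 4, ±30% center windows, 2-kb
    promoter, padj <= 0.05, 75/200-bp bins, 2-kb normalized gene body).
    """

    outdir: str = "run"
    seed: int = 1
    simulate: bool = True
    sim: dict = field(default_factory=dict)  # SimConfig overrides
    # explicit inputs, used when simulate is false:
    peak_files: dict = field(default_factory=dict)  # {condition: {replicate: path}}
    mock_files: dict = field(default_factory=dict)  # {condition: path}
    genome: Optional[str] = None
    genes: Optional[str] = None
    de_table: Optional[str] = None
    contrast_map: dict = field(
        default_factory=lambda: {v: k for k, v in CONTRAST_BY_CONDITION.items()}
    )
    # stage parameters
    min_frac: float = 0.8
    min_support: int = 2
    window_frac: float = 0.3
    upstream_bp: int = 2000
    padj_max: float = 0.05
    min_abs_log2fc: float = 0.0
    exclude_control_flagged: bool = False
    motifs: list = field(default_factory=lambda: ["GTACTRC", "TCTTCTST"])
    bin_center: int = 75
    bin_profile: int = 200
    body_norm: int = 2000
    profile_upstream_bp: int = 2000
    profile_downstream_bp: int = 2000

    @classmethod
    def from_yaml(cls, path, **overrides) -> "RunConfig":
        with open(path) as fh:
            data = yaml.safe_load(fh) or {}
        unknown = set(data) - {f.name for f in dataclasses.fields(cls)}
        if unknown:
            raise ValueError(f"unknown config key(s): {sorted(unknown)}")
        data.update(overrides)
        return cls(**data)

    def validate(self) -> None:
        if not 0.0 < self.min_frac <= 1.0:
            raise ValueError(f"min_frac must be in (0,1], got {self.min_frac}")
        if self.min_support < 1:
            raise ValueError("min_support must be >= 1")
        if self.window_frac <= 0:
            raise ValueError("window_frac must be > 0")
        if not 0.0 < self.padj_max <= 1.0:
            raise ValueError("padj_max must be in (0,1]")
        if self.upstream_bp < 0 or self.min_abs_log2fc < 0:
            raise ValueError("upstream_bp and min_abs_log2fc must be >= 0")
        if not self.simulate:
            missing = [
                name
                for name, val in [
                    ("peak_files", self.peak_files),
                    ("genes", self.genes),
                    ("genome", self.genome),
                    ("de_table", self.de_table),
                ]
                if not val
            ]
            if missing:
                raise ValueError(
                    f"simulate=false requires explicit inputs: {missing}"
                )


def _sha256(path: Path) -> str:
    h = hashlib.sha256()
    with open(path, "rb") as fh:
        for chunk in iter(lambda: fh.read(1 << 16), b""):
            h.update(chunk)
    return h.hexdigest()


def run_all(config: RunConfig) -> dict:
    """Execute every stage in order; returns the manifest dict."""
    config.validate()
    outdir = Path(config.outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    params = dataclasses.asdict(config)
    for key in ("outdir", "peak_files", "mock_files", "genome", "genes", "de_table"):
        params.pop(key, None)  # paths are machine-local; inputs are checksummed
    manifest: dict = {
        "version": __version__,
        "parameters": params,
        "inputs": {},
        "outputs": {},
        "counts": {},
    }
    stale_flag = outdir / "INCOMPLETE"
    stale_flag.write_text("run in progress; outputs below this point are stale\n")

    def _stage(name):
        def deco(fn):
            try:
                result = fn()
            except BaseException as exc:
                raise StageError(name, exc) from exc
            logger.info("stage %s: %s", name, manifest["counts"].get(name, "done"))
            return result

        return deco

    # --- simulate -------------------------------------------------------
    truth = None
    if config.simulate:
        @_stage("simulate")
        def _sim():
            nonlocal truth
            sim_cfg = SimConfig(seed=config.seed, **config.sim)
            paths, truth = simulate(sim_cfg, outdir / "sim")
            config.genome = str(paths["genome"])
            config.genes = str(paths["genes"])
            config.de_table = str(paths["de_table"])
            config.peak_files = {
                cond: {
                    f"R{r}": str(paths[f"peaks_{cond}_R{r}"])
                    for r in range(1, sim_cfg.replicate_count + 1)
                }
                for cond in CONDITIONS
            }
            config.mock_files = {
                cond: str(paths[f"mock_{cond}"]) for cond in CONDITIONS
            }
            manifest["counts"]["simulate"] = {
                "n_true_sites": len(truth["sites"]),
                "n_genes": len(truth["gene_classes"]),
            }

    for key, path in [
        ("genome", config.genome),
        ("genes", config.genes),
        ("de_table", config.de_table),
    ]:
        manifest["inputs"][key] = _sha256(Path(path))
    for cond, reps in config.peak_files.items():
        for rep, path in reps.items():
            manifest["inputs"][f"peaks_{cond}_{rep}"] = _sha256(Path(path))
    for cond, path in config.mock_files.items():
        manifest["inputs"][f"mock_{cond}"] = _sha256(Path(path))

    # --- merge ----------------------------------------------------------
    consensus_by_cond: dict = {}

    @_stage("merge")
    def _merge():
        for cond, reps in sorted(config.peak_files.items()):
            peaks = []
            for rep, path in sorted(reps.items()):
                peaks.extend(read_peaks(path, rep, cond, TAGGED))
            cons = merge_replicates(peaks, config.min_frac, config.min_support)
            consensus_by_cond[cond] = cons
            write_bed(cons, outdir / f"consensus_{cond}.bed")
            pd.DataFrame(
                [
                    {"peak_id": c.peak_id, "support": c.support, "members": ";".join(c.member_ids)}
                    for c in cons
                ]
            ).to_csv(outdir / f"consensus_{cond}_members.tsv", sep="\t", index=False)
        consensus_summary(
            [c for cons in consensus_by_cond.values() for c in cons]
        ).to_csv(outdir / "consensus_summary.tsv", sep="\t", index=False)
        manifest["counts"]["merge"] = {
            cond: len(cons) for cond, cons in consensus_by_cond.items()
        }

    # --- compare --------------------------------------------------------
    presence_by_peak: dict = {}

    @_stage("compare")
    def _compare():
        low_cls, ctrl_cls, venn = classify_presence(
            consensus_by_cond.get(LOW_CU, []),
            consensus_by_cond.get(CONTROL_CU, []),
            config.window_frac,
        )
        mock_peaks = []
        for cond, path in sorted(config.mock_files.items()):
            mock_peaks.extend(read_peaks(path, "mock", cond, UNTAGGED_CONTROL))
        all_cons = consensus_by_cond.get(LOW_CU, []) + consensus_by_cond.get(CONTROL_CU, [])
        flags, n_flagged = flag_control_overlap(all_cons, mock_peaks)
        low_cls = apply_presence_flags(low_cls, flags)
        ctrl_cls = apply_presence_flags(ctrl_cls, flags)
        venn["mock_flagged"] = n_flagged
        with open(outdir / "venn.json", "w") as fh:
            json.dump(venn, fh, indent=1, sort_keys=True)
            fh.write("\n")
        rows = [
            {
                "peak_id": c.consensus_peak.peak_id,
                "condition": c.consensus_peak.condition,
                "presence": c.presence,
                "control_flagged": c.control_flagged,
                "partner": c.matched_partner or "",
            }
            for c in low_cls + ctrl_cls
        ]
        pd.DataFrame(rows).to_csv(outdir / "peak_classes.tsv", sep="\t", index=False)
        presence_by_peak.update(
            {c.consensus_peak.peak_id: c.presence for c in low_cls + ctrl_cls}
        )
        if config.exclude_control_flagged:
            for cond in list(consensus_by_cond):
                consensus_by_cond[cond] = [
                    c for c in consensus_by_cond[cond] if not flags.get(c.peak_id)
                ]
        manifest["counts"]["compare"] = venn

    # --- annotate -------------------------------------------------------
    genes = read_gff3_genes(config.genes)
    gene_by_id = {g.gene_id: g for g in genes}
    links_by_cond: dict = {}

    @_stage("annotate")
    def _annotate():
        import numpy as np

        rows = []
        for cond, cons in sorted(consensus_by_cond.items()):
            links = associate_peaks(cons, genes, config.upstream_bp)
            links_by_cond[cond] = links
            rows.extend(
                {
                    "peak_id": ln.consensus_peak.peak_id,
                    "condition": cond,
                    "gene_id": ln.gene_id,
                    "localization": ln.localization,
                    "signed_distance": ln.signed_distance,
                    "support": ln.consensus_peak.support,
                }
                for ln in links
            )
        pd.DataFrame(rows).to_csv(outdir / "peak_gene_links.tsv", sep="\t", index=False)
        edges = np.arange(-config.upstream_bp, config.upstream_bp + config.bin_profile,
                          config.bin_profile, dtype=float)
        hist_rows = []
        for cond, links in sorted(links_by_cond.items()):
            counts = tss_distance_histogram(links, edges)
            hist_rows.extend(
                {"condition": cond, "bin_lo": int(edges[i]), "bin_hi": int(edges[i + 1]),
                 "count": int(counts[i])}
                for i in range(len(counts))
            )
        pd.DataFrame(hist_rows).to_csv(
            outdir / "tss_distance_histogram.tsv", sep="\t", index=False
        )
        manifest["counts"]["annotate"] = {
            cond: {
                "links": len(links),
                "genes": len({ln.gene_id for ln in links}),
            }
            for cond, links in links_by_cond.items()
        }

    # --- integrate ------------------------------------------------------
    calls = []

    @_stage("integrate")
    def _integrate():
        nonlocal calls
        de = read_de_table(config.de_table)
        classes = classify_regulation(
            de, config.padj_max, config.min_abs_log2fc, config.contrast_map
        )
        de_by_gene = {
            (r.gene_id, config.contrast_map.get(r.contrast, r.contrast)): r for r in de
        }
        calls, counts = call_targets(
            links_by_cond, classes, de_by_gene, "any", presence_by_peak
        )
        pd.DataFrame(
            [
                {
                    "gene_id": c.gene_id,
                    "condition": c.condition,
                    "verdict": c.verdict,
                    "peaks": ";".join(c.peak_ids),
                    "log2fc": c.log2fc,
                    "padj": "" if c.padj is None else c.padj,
                }
                for c in calls
            ]
        ).to_csv(outdir / "target_calls.tsv", sep="\t", index=False)
        results = {"set_sizes": counts, "thresholds": {
            "padj_max": config.padj_max, "min_abs_log2fc": config.min_abs_log2fc}}
        if truth is not None:
            universe = sorted(gene_by_id)
            called_low = sorted(
                {c.gene_id for c in calls if c.condition == LOW_CU
                 and c.verdict == "direct_activation_candidate"}
            )
            truth_act = truth["target_classes"][LOW_CU]["activated"]
            ot = overlap_test(universe, called_low, truth_act)
            results["overlap_called_vs_true_activated_low_cu"] = dataclasses.asdict(ot)
        with open(outdir / "integration.json", "w") as fh:
            json.dump(results, fh, indent=1, sort_keys=True)
            fh.write("\n")
        manifest["counts"]["integrate"] = counts

    # --- motifs ---------------------------------------------------------
    @_stage("motifs")
    def _motifs():
        import numpy as np
        from pyfaidx import Fasta

        genome = {rec.name: str(rec[:]) for rec in Fasta(config.genome)}
        motif_counts = {}
        gff_path = outdir / "motif_sites.gff3"
        with open(gff_path, "w") as gff:
            gff.write("##gff-version 3\n")
            for pattern in config.motifs:
                cons = consensus_by_cond.get(LOW_CU, [])
                sites, per_peak, hist = sites_per_peak(cons, genome, pattern)
                for s in sites:
                    iv = s.interval
                    gff.write(
                        f"{iv.chrom}\tscan\tnucleotide_motif\t{iv.start + 1}\t{iv.end}\t.\t"
                        f"{s.strand}\t.\tName={pattern};peak={s.peak_id};"
                        f"match={s.matched_text}\n"
                    )
                edges_c, dens = center_distance_density(sites, config.bin_center)
                pd.DataFrame(
                    {
                        "bin_lo": edges_c[:-1],
                        "bin_hi": edges_c[1:],
                        "density": dens,
                    }
                ).to_csv(
                    outdir / f"motif_{pattern}_center_distance.tsv", sep="\t", index=False
                )
                # pair each site with the closest gene linked to its peak
                best_gene = {}
                for ln in links_by_cond.get(LOW_CU, []):
                    pid = ln.consensus_peak.peak_id
                    if (
                        pid not in best_gene
                        or abs(ln.signed_distance) < best_gene[pid][1]
                    ):
                        best_gene[pid] = (ln.gene_id, abs(ln.signed_distance))
                linked = [
                    (s, best_gene[s.peak_id][0])
                    for s in sites
                    if s.peak_id in best_gene
                ]
                edges_p, counts, skipped = normalized_position_profile(
                    linked,
                    gene_by_id,
                    config.profile_upstream_bp,
                    config.profile_downstream_bp,
                    config.body_norm,
                    config.bin_profile,
                )
                pd.DataFrame(
                    {
                        "bin_lo": edges_p[:-1].astype(int),
                        "bin_hi": edges_p[1:].astype(int),
                        "count": counts,
                    }
                ).to_csv(
                    outdir / f"motif_{pattern}_position_profile.tsv", sep="\t", index=False
                )
                pd.DataFrame(
                    sorted(hist.items()), columns=["copies_per_peak", "n_peaks"]
                ).to_csv(
                    outdir / f"motif_{pattern}_copies_per_peak.tsv", sep="\t", index=False
                )
                motif_counts[pattern] = {
                    "sites_in_peaks": len(sites),
                    "peaks_with_site": sum(1 for v in per_peak.values() if v > 0),
                    "profile_sites": int(counts.sum()),
                }
        manifest["counts"]["motifs"] = motif_counts

    # --- manifest -------------------------------------------------------
    for path in sorted(outdir.glob("*")):
        if path.is_file() and path.name not in ("manifest.json", "INCOMPLETE"):
            manifest["outputs"][path.name] = _sha256(path)
    with open(outdir / "manifest.json", "w") as fh:
        json.dump(manifest, fh, indent=1, sort_keys=True)
        fh.write("\n")
    stale_flag.unlink(missing_ok=True)
    return manifest
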