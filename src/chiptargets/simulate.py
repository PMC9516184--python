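"""Synthetic dataset generator with known ground truth.

Emulates the downstream products of a replicated TF ChIP-seq /
genotype-contrast RNA-seq study: a small random genome with
non-overlapping genes, true binding sites planted in promoters (each
containing a concrete instance of the degenerate binding motif),
per-replicate peak calls with center/width jitter and replicate
dropout, uniform background peaks, single-replicate mock (untagged
control) peak sets, and a WT-vs-mutant differential-expression table
for two conditions. Everything derives from one seeded random stream,
consumed in a fixed order, so a given seed reproduces the file set
byte for byte.

The DE table is generated from negative-binomial counts with a planted
genotype effect for bound-activated/-repressed genes and tested with a
Wald-style two-group normal approximation on log counts plus
Benjamini-Hochberg adjustment; the pipeline only consumes (log2fc,
padj), so no attempt is made to mimic a shrinkage-based DE model.
"""

from __future__ import annotations

import json
from dataclasses import asdict, dataclass, field
from pathlib import Path
from typing import Optional, Sequence

import numpy as np
import pandas as pd
from scipy.stats import norm
from statsmodels.stats.multitest import multipletests

from .consensus import ConsensusPeak
from .io import (
    CONDITIONS,
    CONTROL_CU,
    LOW_CU,
    TAGGED,
    UNTAGGED_CONTROL,
    GeneModel,
    GenomicInterval,
)
from .motif import IUPAC_CODES, IupacMotif

CONTRAST_BY_CONDITION = {LOW_CU: "wt_vs_mut_lowcu", CONTROL_CU: "wt_vs_mut_controlcu"}

_BASES = np.frombuffer(b"ACGT", dtype=np.uint8)


class ConfigError(ValueError):
    pass


@dataclass
class SimConfig:
    """Generator parameters; defaults are the package's reference scenario.

    The reference scenario plants 200 true binding sites across 260
    genes on two 700-kb chromosomes, emits each site in 4 replicates
    with 20-bp center jitter and 20% replicate dropout plus 100 uniform
    background peaks per replicate, and plants a 2^3-fold wild-type/mutant
    expression effect for 50 bound-activated and 50 bound-repressed genes
    under the low-Cu contrast (the control contrast is null).
    """

    seed: int = 1
    n_chrom: int = 2
    chrom_len_bp: int = 700_000
    n_genes: int = 260
    n_true_sites: int = 200
    frac_sites_lowcu_only: float = 0.15
    replicate_count: int = 4
    jitter_sd_bp: float = 20.0
    replicate_dropout_prob: float = 0.2
    background_peaks_per_replicate: int = 100
    mock_peaks_per_condition: int = 30
    motif: str = "GTACTRC"
    site_center_upstream_bp: int = 150  # planted site center relative to TSS
    site_width_min: int = 240
    site_width_max: int = 360
    de_effect_log2fc: float = 3.0
    de_dispersion: float = 0.05
    de_replicates: int = 3
    n_bound_activated: int = 50
    n_bound_repressed: int = 50
    n_bound_unchanged: int = 100
    n_unbound_de: int = 40

    def validate(self) -> None:
        if self.seed < 0:
            raise ConfigError("seed must be nonnegative")
        for name in (
            "n_chrom", "chrom_len_bp", "n_genes", "n_true_sites",
            "replicate_count", "background_peaks_per_replicate",
            "mock_peaks_per_condition", "de_replicates",
        ):
            if getattr(self, name) < 0 or (name in ("n_chrom", "chrom_len_bp") and getattr(self, name) <= 0):
                raise ConfigError(f"{name} must be nonnegative")
        for name in ("frac_sites_lowcu_only", "replicate_dropout_prob"):
            if not 0.0 <= getattr(self, name) <= 1.0:
                raise ConfigError(f"{name} must be in [0, 1]")
        if self.n_true_sites > self.n_genes:
            raise ConfigError("n_true_sites cannot exceed n_genes")
        if (
            self.n_bound_activated + self.n_bound_repressed + self.n_bound_unchanged
            != self.n_true_sites
        ):
            raise ConfigError(
                "n_bound_activated + n_bound_repressed + n_bound_unchanged "
                "must equal n_true_sites"
            )
        if self.n_unbound_de > self.n_genes - self.n_true_sites:
            raise ConfigError("n_unbound_de exceeds the number of unbound genes")
        IupacMotif(self.motif)  # raises on an invalid pattern
        # sequential placement needs on average ~(gene + gap + margins) bp/gene
        per_chrom = -(-self.n_genes // self.n_chrom)
        if per_chrom * (2500 + 2500) + 2 * 3000 > self.chrom_len_bp:
            raise ConfigError(
                f"{self.n_genes} genes do not fit in {self.n_chrom} x "
                f"{self.chrom_len_bp} bp chromosomes"
            )


@dataclass(frozen=True)
class TrueSite:
    site_id: str
    interval: GenomicInterval
    gene_id: str
    presence: str  # "shared" or "low_cu_only"


def _place_genes(cfg: SimConfig, rng: np.random.Generator) -> list[GeneModel]:
    genes = []
    per_chrom = [cfg.n_genes // cfg.n_chrom] * cfg.n_chrom
    for i in range(cfg.n_genes % cfg.n_chrom):
        per_chrom[i] += 1
    gid = 0
    for ci in range(cfg.n_chrom):
        chrom = f"chr{ci + 1}"
        pos = 3000
        for _ in range(per_chrom[ci]):
            pos += int(rng.integers(1500, 2501))  # intergenic gap (promoter room)
            length = int(rng.integers(1000, 2501))
            strand = "+" if rng.random() < 0.5 else "-"
            if pos + length > cfg.chrom_len_bp - 3000:
                raise ConfigError(
                    f"gene placement overflowed {chrom}; increase chrom_len_bp"
                )
            gid += 1
            genes.append(
                GeneModel(f"GENE{gid:04d}", GenomicInterval(chrom, pos, pos + length, strand))
            )
            pos += length
    return genes


def _concrete_motif(pattern: str, rng: np.random.Generator) -> str:
    return "".join(
        sorted(IUPAC_CODES[ch] - {"N"})[int(rng.integers(len(IUPAC_CODES[ch] - {"N"})))]
        if len(IUPAC_CODES[ch]) > 1
        else ch
        for ch in pattern
    )


def simulate(config: SimConfig, outdir) -> tuple[dict[str, Path], dict]:
    """Generate the full synthetic file set under ``outdir``.

    Returns ({file key: path}, truth dict). The truth dict is also
    written to ``truth.json``. Emitted files: ``genome.fa``,
    ``genes.gff3``, ``peaks_<condition>_R<k>.narrowPeak``,
    ``mock_<condition>.narrowPeak``, ``de_table.tsv``, ``truth.json``.
    """
    config.validate()
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    rng = np.random.default_rng(config.seed)
    motif = IupacMotif(config.motif)

    # 1. genes
    genes = _place_genes(config, rng)
    gene_by_id = {g.gene_id: g for g in genes}

    # 2. bound genes, their regulation classes and site condition presence
    order = rng.permutation(config.n_genes)
    bound_idx = order[: config.n_true_sites]
    unbound_idx = order[config.n_true_sites :]
    classes: dict[str, str] = {}
    for k, gi in enumerate(bound_idx):
        gene = genes[gi]
        if k < config.n_bound_activated:
            classes[gene.gene_id] = "activated"
        elif k < config.n_bound_activated + config.n_bound_repressed:
            classes[gene.gene_id] = "repressed"
        else:
            classes[gene.gene_id] = "unchanged"
    for k, gi in enumerate(unbound_idx[: config.n_unbound_de]):
        classes[genes[gi].gene_id] = "activated" if k % 2 == 0 else "repressed"
    for gi in unbound_idx[config.n_unbound_de :]:
        classes[genes[gi].gene_id] = "unchanged"

    n_low_only = int(round(config.frac_sites_lowcu_only * config.n_true_sites))
    presence_order = rng.permutation(config.n_true_sites)
    sites: list[TrueSite] = []
    for k, bi in enumerate(bound_idx):
        gene = genes[bi]
        width = int(rng.integers(config.site_width_min, config.site_width_max + 1))
        if gene.strand == "+":
            center = gene.tss - config.site_center_upstream_bp
        else:
            center = gene.tss + config.site_center_upstream_bp
        start = int(center - width // 2)
        iv = GenomicInterval(gene.interval.chrom, start, start + width)
        pres = "low_cu_only" if presence_order[k] < n_low_only else "shared"
        sites.append(TrueSite(f"site{k + 1:04d}", iv, gene.gene_id, pres))

    # 3. genome with planted motif instances at site centers
    chrom_arrays = {
        f"chr{ci + 1}": _BASES[rng.integers(0, 4, size=config.chrom_len_bp)].copy()
        for ci in range(config.n_chrom)
    }
    for site in sites:
        inst = _concrete_motif(motif.pattern, rng)
        pos = int(site.interval.center - len(inst) / 2)
        chrom_arrays[site.interval.chrom][pos : pos + len(inst)] = np.frombuffer(
            inst.encode(), dtype=np.uint8
        )
    genome = {c: arr.tobytes().decode() for c, arr in chrom_arrays.items()}

    # 4. replicate + background peaks per condition, mock peaks
    forbidden: dict[str, list[tuple[int, int]]] = {}
    for site in sites:
        forbidden.setdefault(site.interval.chrom, []).append(
            (site.interval.start - 600, site.interval.end + 600)
        )

    def _away_from_sites(chrom: str, start: int, end: int) -> bool:
        return all(end <= lo or start >= hi for lo, hi in forbidden.get(chrom, []))

    peak_files: dict[tuple[str, str], list[tuple]] = {}
    chrom_names = sorted(genome)
    for condition in CONDITIONS:
        present = [
            s for s in sites if s.presence == "shared" or condition == LOW_CU
        ]
        for rep in range(1, config.replicate_count + 1):
            rows = []
            for site in present:
                drop = rng.random() < config.replicate_dropout_prob
                dc = rng.normal(0, config.jitter_sd_bp) if config.jitter_sd_bp else 0.0
                dw = rng.normal(0, config.jitter_sd_bp) if config.jitter_sd_bp else 0.0
                if drop:
                    continue
                width = max(100, int(round(site.interval.length + dw)))
                center = site.interval.center + dc
                start = int(round(center - width / 2))
                score = float(np.round(rng.uniform(20, 200), 2))
                rows.append((site.interval.chrom, start, start + width, score))
            for _ in range(config.background_peaks_per_replicate):
                while True:
                    chrom = chrom_names[int(rng.integers(len(chrom_names)))]
                    width = int(rng.integers(150, 401))
                    start = int(rng.integers(0, config.chrom_len_bp - width))
                    if _away_from_sites(chrom, start, start + width):
                        break
                score = float(np.round(rng.uniform(20, 200), 2))
                rows.append((chrom, start, start + width, score))
            rows.sort(key=lambda r: (r[0], r[1], r[2]))
            peak_files[(condition, f"R{rep}")] = rows

    mock_files: dict[str, list[tuple]] = {}
    for condition in CONDITIONS:
        rows = []
        for _ in range(config.mock_peaks_per_condition):
            chrom = chrom_names[int(rng.integers(len(chrom_names)))]
            width = int(rng.integers(120, 201))
            start = int(rng.integers(0, config.chrom_len_bp - width))
            score = float(np.round(rng.uniform(5, 50), 2))
            rows.append((chrom, start, start + width, score))
        rows.sort(key=lambda r: (r[0], r[1], r[2]))
        mock_files[condition] = rows

    # 5. DE table (negative binomial counts -> Wald z on log2 counts -> BH)
    base_mu = np.exp(rng.normal(np.log(200.0), 0.8, size=config.n_genes))
    de_rows = []
    for condition in CONDITIONS:
        contrast = CONTRAST_BY_CONDITION[condition]
        lfcs = np.zeros(config.n_genes)
        if condition == LOW_CU:
            for gi, gene in enumerate(genes):
                cls = classes[gene.gene_id]
                if cls == "activated":
                    lfcs[gi] = config.de_effect_log2fc
                elif cls == "repressed":
                    lfcs[gi] = -config.de_effect_log2fc
        alpha = config.de_dispersion
        nrep = config.de_replicates
        mu_mut = base_mu
        mu_wt = base_mu * np.power(2.0, lfcs)

        def _nb(mu):
            n = 1.0 / alpha
            p = n / (n + mu)
            return rng.negative_binomial(n, p[:, None], size=(config.n_genes, nrep))

        wt = _nb(mu_wt)
        mut = _nb(mu_mut)
        lwt, lmut = np.log2(wt + 1.0), np.log2(mut + 1.0)
        lfc_hat = lwt.mean(axis=1) - lmut.mean(axis=1)
        se = np.sqrt(lwt.var(axis=1, ddof=1) / nrep + lmut.var(axis=1, ddof=1) / nrep)
        se = np.maximum(se, 1e-8)
        pvals = 2.0 * norm.sf(np.abs(lfc_hat) / se)
        padj = multipletests(pvals, method="fdr_bh")[1]
        base_mean = np.concatenate([wt, mut], axis=1).mean(axis=1)
        for gi, gene in enumerate(genes):
            de_rows.append(
                {
                    "gene_id": gene.gene_id,
                    "contrast": contrast,
                    "log2fc": round(float(lfc_hat[gi]), 6),
                    "padj": f"{padj[gi]:.6g}",
                    "base_mean": round(float(base_mean[gi]), 3),
                }
            )

    # 6. write everything
    paths: dict[str, Path] = {}

    fa = outdir / "genome.fa"
    with open(fa, "w") as fh:
        for chrom in chrom_names:
            fh.write(f">{chrom}\n")
            seq = genome[chrom]
            for i in range(0, len(seq), 60):
                fh.write(seq[i : i + 60] + "\n")
    paths["genome"] = fa

    gff = outdir / "genes.gff3"
    with open(gff, "w") as fh:
        fh.write("##gff-version 3\n")
        for g in sorted(genes, key=lambda g: (g.interval.chrom, g.interval.start)):
            iv = g.interval
            fh.write(
                f"{iv.chrom}\tsim\tgene\t{iv.start + 1}\t{iv.end}\t.\t{iv.strand}\t.\t"
                f"ID={g.gene_id};Name={g.gene_id}\n"
            )
    paths["genes"] = gff

    def _write_narrowpeak(path: Path, rows, prefix: str) -> None:
        with open(path, "w") as fh:
            for i, (chrom, start, end, score) in enumerate(rows, 1):
                summit = (end - start) // 2
                fh.write(
                    f"{chrom}\t{start}\t{end}\t{prefix}_{i}\t{score:g}\t.\t"
                    f"{score:g}\t-1\t-1\t{summit}\n"
                )

    for (condition, rep), rows in peak_files.items():
        p = outdir / f"peaks_{condition}_{rep}.narrowPeak"
        _write_narrowpeak(p, rows, f"{condition}_{rep}")
        paths[f"peaks_{condition}_{rep}"] = p
    for condition, rows in mock_files.items():
        p = outdir / f"mock_{condition}.narrowPeak"
        _write_narrowpeak(p, rows, f"mock_{condition}")
        paths[f"mock_{condition}"] = p

    de_path = outdir / "de_table.tsv"
    pd.DataFrame(de_rows).to_csv(de_path, sep="\t", index=False)
    paths["de_table"] = de_path

    truth = {
        "seed": config.seed,
        "config": asdict(config),
        "sites": [
            {
                "site_id": s.site_id,
                "chrom": s.interval.chrom,
                "start": s.interval.start,
                "end": s.interval.end,
                "gene_id": s.gene_id,
                "presence": s.presence,
            }
            for s in sites
        ],
        "gene_classes": {g.gene_id: classes[g.gene_id] for g in genes},
        "bound_genes": sorted(s.gene_id for s in sites),
        "target_classes": {
            LOW_CU: {
                "activated": sorted(
                    s.gene_id for s in sites if classes[s.gene_id] == "activated"
                ),
                "repressed": sorted(
                    s.gene_id for s in sites if classes[s.gene_id] == "repressed"
                ),
            },
            CONTROL_CU: {"activated": [], "repressed": []},
        },
    }
    truth_path = outdir / "truth.json"
    with open(truth_path, "w") as fh:
        json.dump(truth, fh, indent=1, sort_keys=True)
        fh.write("\n")
    paths["truth"] = truth_path
    return paths, truth


def score_against_truth(
    consensus_by_condition: dict[str, Sequence[ConsensusPeak]],
    truth: dict,
    target_calls: Optional[Sequence] = None,
) -> dict:
    """Precision/recall of site recovery (and optionally target calls).

    A true site counts as recovered when the center of some consensus
    peak of the matching condition lies inside it; a consensus peak is a
    true positive when its center lies inside some true site present
    under its condition. Empty consensus output gives recall 0 and a
    missing (None) precision.
    """
    out: dict = {"site_recovery": {}}
    sites = truth["sites"]
    for condition, consensus in consensus_by_condition.items():
        cond_sites = [
            s
            for s in sites
            if s["presence"] == "shared"
            or (condition == LOW_CU and s["presence"] == "low_cu_only")
        ]
        hit = set()
        tp = 0
        for c in consensus:
            center = c.interval.center
            matched = False
            for s in cond_sites:
                if s["chrom"] == c.interval.chrom and s["start"] <= center < s["end"]:
                    hit.add(s["site_id"])
                    matched = True
            tp += matched
        out["site_recovery"][condition] = {
            "n_true_sites": len(cond_sites),
            "n_consensus": len(consensus),
            "recall": len(hit) / len(cond_sites) if cond_sites else None,
            "precision": tp / len(consensus) if consensus else None,
        }
    if target_calls is not None:
        truth_pairs = {
            (g, cond, cls)
            for cond, d in truth["target_classes"].items()
            for cls, gene_ids in d.items()
            for g in gene_ids
        }
        call_pairs = {
            (
                c.gene_id,
                c.condition,
                "activated" if c.verdict == "direct_activation_candidate" else "repressed",
            )
            for c in target_calls
        }
        tp = len(truth_pairs & call_pairs)
        out["target_calls"] = {
            "n_truth": len(truth_pairs),
            "n_called": len(call_pairs),
            "precision": tp / len(call_pairs) if call_pairs else None,
            "recall": tp / len(truth_pairs) if truth_pairs else None,
        }
    return out
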