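"""Synthetic multi-omics generator with planted effect structure.

Generates every input the pipeline consumes — gene models, consensus ATAC
peaks, chromatin-state segments, region sequences with planted motif
instances, count matrices, and lifespan tables — together with truth tables
listing every planted effect, so that each analysis stage can be scored
against a known ground truth.

The planted structure mirrors the biology the pipeline is built to detect:
accessibility changes concentrated in distal non-coding (distNC) regions
that close during aging and re-open under reduced insulin/IGF-like
signaling (anti-concordant across the two contrasts), concordant expression
changes at the closest genes, an "enhancer" chromatin state preferentially
covering the planted regions, a TF motif planted in the opening regions,
and survival times with group-specific target medians.

Counts are negative binomial and lifespans Weibull; these are modelling
choices of the test harness, not claims about real data (see the methods
note).  All randomness flows from the single config seed through
documented sub-streams.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict
from pathlib import Path
from typing import Dict, List, Mapping, Optional, Sequence, Set, Tuple

import numpy as np
import pandas as pd

from . import io as tio
from .annotation import GeneModel, RegionAnnotator
from .differential import CountMatrix
from .intervals import GenomicInterval, RegionSet
from .motifs import BASES, PWM, write_homer_motifs

# worm-like AT-rich base composition (A, C, G, T)
DEFAULT_BASE_FREQS = (0.32, 0.18, 0.18, 0.32)

STATE_LABELS = (
    "1. Active promoter",
    "2. Enhancer 1",
    "3. Enhancer 2",
    "4. Transcribed",
    "5. PC repressed 1",
    "6. PC repressed 2",
    "7. Heterochromatin",
    "8. Quiescent",
)
ENHANCER_STATES = ("2. Enhancer 1", "3. Enhancer 2")


@dataclass
class SimulationConfig:
    """All knobs of the generator; defaults are the study conditions.

    Accessibility effects are 4-fold (``effect_log2fc = 2``) on negative
    binomial counts with common dispersion 0.1 around a mean of 100, three
    replicates per condition.  30% of distNC peaks close with age and 60% of
    those re-open under reduced IIS; promoter peaks receive independent
    effects in the two contrasts so their cross-condition overlap is null.
    Lifespan groups follow a control median of 17 days, a long-lived 2x
    condition, and a knockdown condition configured as a 50% reduction of
    the long-lived median, with steep Weibull (shape 4) mortality.
    """

    seed: int = 0
    # genome
    n_chroms: int = 3
    chrom_length: int = 1_500_000
    n_genes: int = 300
    n_peaks: int = 1000
    peak_width: int = 200
    category_mix: Dict[str, float] = field(
        # no 5'UTR share: short 5'UTRs sit inside the promoter window, which
        # wins by precedence, so a planted 5'UTR peak would classify Promoter
        default_factory=lambda: {
            "Promoter": 0.25,
            "3'UTR": 0.05,
            "Exon": 0.05,
            "Intron": 0.28,
            "Distal Intergenic": 0.37,
        }
    )
    base_freqs: Tuple[float, float, float, float] = DEFAULT_BASE_FREQS
    # counts
    nb_dispersion: float = 0.1
    baseline_mean: float = 100.0
    baseline_log_sd: float = 0.4
    n_replicates: int = 3
    depth_log_sd: float = 0.15
    # effect model
    effect_log2fc: float = 2.0
    gene_effect_log2fc: float = 2.0
    frac_distnc_aging_closing: float = 0.30
    anti_concordance_rate: float = 0.60
    frac_distnc_independent: float = 0.05
    frac_promoter_effects: float = 0.15
    gene_concordant_fraction: float = 0.80
    gene_discordant_fraction: float = 0.10
    # motif
    motif_length: int = 10
    motif_planting_fraction: float = 0.50
    motif_info: float = 0.85  # probability mass on the consensus base
    # chromatin states
    enhancer_state_prob: float = 0.80
    state_segment_length: int = 2000
    # survival
    survival_medians: Dict[str, float] = field(
        default_factory=lambda: {
            "control": 17.0,
            "longlived": 34.0,
            "longlived_kd": 17.0,
        }
    )
    weibull_shape: float = 4.0
    censoring_rate: float = 0.10
    n_per_group: int = 150

    def __post_init__(self) -> None:
        for name in (
            "frac_distnc_aging_closing",
            "anti_concordance_rate",
            "frac_distnc_independent",
            "frac_promoter_effects",
            "gene_concordant_fraction",
            "gene_discordant_fraction",
            "motif_planting_fraction",
            "enhancer_state_prob",
            "censoring_rate",
        ):
            v = getattr(self, name)
            if not (0.0 <= v <= 1.0):
                raise ValueError(f"{name} must be in [0, 1], got {v}")
        if any(m <= 0 for m in self.survival_medians.values()):
            raise ValueError("survival medians must be > 0")
        if self.nb_dispersion < 0:
            raise ValueError("dispersion must be >= 0")
        if abs(sum(self.category_mix.values()) - 1.0) > 1e-6:
            raise ValueError("category_mix fractions must sum to 1")

    def rng(self, stream: str) -> np.random.Generator:
        """Deterministic sub-stream derived from the config seed."""
        h = int.from_bytes(stream.encode(), "big") % (2**31)
        return np.random.default_rng(np.random.SeedSequence([self.seed, h]))


@dataclass
class SimulatedData:
    """Everything simulate_genome produces, plus the planted truth."""

    config: SimulationConfig
    genes: List[GeneModel]
    peaks: RegionSet
    annotations: pd.DataFrame
    states: pd.DataFrame
    sequences: Dict[str, str]
    motif: PWM
    truth: Dict


# ---------------------------------------------------------------------------
# genome layout
# ---------------------------------------------------------------------------


def _lay_genes(cfg: SimulationConfig, rng: np.random.Generator) -> List[GeneModel]:
    """Non-overlapping genes with UTR/exon/intron structure."""
    genes: List[GeneModel] = []
    per_chrom = int(np.ceil(cfg.n_genes / cfg.n_chroms))
    gid = 0
    for c in range(cfg.n_chroms):
        chrom = f"chr{c + 1}"
        slot = cfg.chrom_length // per_chrom
        for k in range(per_chrom):
            if gid >= cfg.n_genes:
                break
            gid += 1
            strand = "+" if rng.random() < 0.5 else "-"
            utr5_len = int(rng.integers(100, 300))
            utr3_len = int(rng.integers(150, 400))
            n_coding = int(rng.integers(2, 5))
            exon_lens = rng.integers(120, 500, size=n_coding)
            intron_lens = rng.integers(300, 900, size=n_coding)
            body = utr5_len + utr3_len + int(exon_lens.sum() + intron_lens.sum())
            # keep the gene away from slot edges so promoter windows stay
            # inside intergenic space of this slot
            margin = 4000
            lo = k * slot + margin
            hi = (k + 1) * slot - margin - body
            if hi <= lo:
                continue
            start = int(rng.integers(lo, hi))
            # genomic layout 5'->3' on the + strand orientation
            pieces: List[Tuple[str, int]] = [("5'UTR", utr5_len)]
            for i in range(n_coding):
                pieces.append(("Exon", int(exon_lens[i])))
                if i < n_coding - 1:
                    pieces.append(("Intron", int(intron_lens[i])))
            pieces.append(("3'UTR", utr3_len))
            if strand == "-":
                pieces = pieces[::-1]
            pos = start
            exons, utr5, utr3 = [], [], []
            for kind, ln in pieces:
                iv = (pos, pos + ln)
                if kind == "Exon":
                    exons.append(iv)
                elif kind == "5'UTR":
                    utr5.append(iv)
                    exons.append(iv)  # UTRs are exonic sequence
                elif kind == "3'UTR":
                    utr3.append(iv)
                    exons.append(iv)
                pos += ln
            # merge adjacent exonic pieces so the exon list is non-overlapping
            merged = []
            for iv in sorted(exons):
                if merged and iv[0] <= merged[-1][1]:
                    merged[-1] = (merged[-1][0], max(merged[-1][1], iv[1]))
                else:
                    merged.append(iv)
            genes.append(
                GeneModel(
                    gene_id=f"gene_{gid:05d}",
                    chrom=chrom,
                    strand=strand,
                    gene_span=(start, pos),
                    exons=tuple(merged),
                    five_prime_utrs=tuple(utr5),
                    three_prime_utrs=tuple(utr3),
                )
            )
    return genes


def _place_peaks(
    cfg: SimulationConfig,
    genes: List[GeneModel],
    rng: np.random.Generator,
) -> RegionSet:
    """Peaks placed to hit the configured genomic-category mix."""
    by_chrom: Dict[str, List[GeneModel]] = {}
    for g in genes:
        by_chrom.setdefault(g.chrom, []).append(g)
    w = cfg.peak_width
    half = w // 2

    def _zone(category: str, g: GeneModel) -> Optional[Tuple[int, int]]:
        if category == "Promoter":
            ps, pe = g.promoter_window(1500, 500)
            return ps, pe
        if category == "5'UTR":
            ivs = g.five_prime_utrs
        elif category == "3'UTR":
            ivs = g.three_prime_utrs
        elif category == "Exon":
            # interior coding exons only (UTR pieces classify as UTR first)
            ivs = tuple(
                iv
                for iv in g.exons
                if iv not in g.five_prime_utrs and iv not in g.three_prime_utrs
            )
        elif category == "Intron":
            ex = sorted(g.exons)
            ivs = tuple(
                (ex[i][1], ex[i + 1][0])
                for i in range(len(ex) - 1)
                if ex[i + 1][0] - ex[i][1] > w + 20
            )
        else:
            return None
        ivs = tuple(iv for iv in ivs if iv[1] - iv[0] > w + 8)
        if not ivs:
            return None
        return ivs[int(rng.integers(0, len(ivs)))]

    cats = list(cfg.category_mix)
    probs = np.array([cfg.category_mix[c] for c in cats])
    peaks: List[GenomicInterval] = []
    occupied: Dict[str, List[Tuple[int, int]]] = {}
    attempts = 0
    while len(peaks) < cfg.n_peaks:
        attempts += 1
        if attempts > cfg.n_peaks * 60:
            raise ValueError(
                "could not place the requested peaks; use a larger genome "
                "or fewer peaks"
            )
        category = cats[int(rng.choice(len(cats), p=probs))]
        chrom = f"chr{int(rng.integers(1, cfg.n_chroms + 1))}"
        cgenes = by_chrom.get(chrom, [])
        if category == "Distal Intergenic":
            start = int(rng.integers(0, cfg.chrom_length - w))
            iv = (start, start + w)
            # must be clear of every gene span and promoter window
            bad = any(
                iv[0] < g.promoter_window(1500, 500)[1] + 10
                and g.promoter_window(1500, 500)[0] - 10 < iv[1]
                or (iv[0] < g.gene_span[1] + 10 and g.gene_span[0] - 10 < iv[1])
                for g in cgenes
            )
            if bad:
                continue
        else:
            if not cgenes:
                continue
            g = cgenes[int(rng.integers(0, len(cgenes)))]
            zone = _zone(category, g)
            if zone is None:
                continue
            zs, ze = zone
            if ze - zs <= w:
                continue
            start = int(rng.integers(zs, ze - w))
            iv = (start, start + w)
            if category != "Promoter":
                # stay clear of every promoter window (precedence would win)
                if any(
                    iv[0] < gg.promoter_window(1500, 500)[1]
                    and gg.promoter_window(1500, 500)[0] < iv[1]
                    for gg in cgenes
                ):
                    continue
        if any(iv[0] < e and s < iv[1] for s, e in occupied.get(chrom, [])):
            continue
        occupied.setdefault(chrom, []).append(iv)
        peaks.append(
            GenomicInterval(chrom, iv[0], iv[1], id=f"peak_{len(peaks) + 1:05d}")
        )
    return RegionSet(peaks)


# ---------------------------------------------------------------------------
# effects, states, sequences
# ---------------------------------------------------------------------------


def _random_pwm(cfg: SimulationConfig, rng: np.random.Generator, name: str) -> PWM:
    consensus = rng.integers(0, 4, size=cfg.motif_length)
    m = np.full((cfg.motif_length, 4), (1 - cfg.motif_info) / 3)
    m[np.arange(cfg.motif_length), consensus] = cfg.motif_info
    return PWM(name=name, matrix=m, background=np.asarray(cfg.base_freqs))


def _sample_motif_instance(pwm: PWM, rng: np.random.Generator) -> str:
    return "".join(
        BASES[rng.choice(4, p=row / row.sum())] for row in pwm.matrix
    )


def _plant_effects(
    cfg: SimulationConfig, annotations: pd.DataFrame, rng: np.random.Generator
) -> pd.DataFrame:
    """Planted accessibility effects per peak and contrast.

    Returns a table (peak_id, contrast, direction, log2fc).  Contrasts:
    ``aging`` (old vs young; "closed" means less accessible with age) and
    ``iis`` (reduced-IIS mutant vs wild type).
    """
    distnc = annotations.loc[annotations["is_distnc"], "id"].to_list()
    prom = annotations.loc[annotations["is_prom"], "id"].to_list()
    fx: List[Dict] = []

    n_close = int(round(cfg.frac_distnc_aging_closing * len(distnc)))
    closing = list(rng.choice(distnc, size=n_close, replace=False))
    n_anti = int(round(cfg.anti_concordance_rate * n_close))
    reopened = set(rng.choice(closing, size=n_anti, replace=False))
    for pid in closing:
        fx.append(
            {
                "peak_id": pid,
                "contrast": "aging",
                "direction": "closed",
                "log2fc": -cfg.effect_log2fc,
            }
        )
        if pid in reopened:
            fx.append(
                {
                    "peak_id": pid,
                    "contrast": "iis",
                    "direction": "open",
                    "log2fc": cfg.effect_log2fc,
                }
            )
    # independent distNC effects (noise structure, both contrasts)
    rest = [p for p in distnc if p not in set(closing)]
    n_ind = int(round(cfg.frac_distnc_independent * len(distnc)))
    for contrast in ("aging", "iis"):
        if n_ind == 0 or not rest:
            continue
        chosen = rng.choice(rest, size=min(n_ind, len(rest)), replace=False)
        for pid in chosen:
            up = rng.random() < 0.5
            fx.append(
                {
                    "peak_id": pid,
                    "contrast": contrast,
                    "direction": "open" if up else "closed",
                    "log2fc": cfg.effect_log2fc if up else -cfg.effect_log2fc,
                }
            )
    # promoters: effects drawn independently per contrast -> null overlap
    n_prom = int(round(cfg.frac_promoter_effects * len(prom)))
    for contrast in ("aging", "iis"):
        if n_prom == 0 or not prom:
            continue
        chosen = rng.choice(prom, size=n_prom, replace=False)
        for pid in chosen:
            up = rng.random() < 0.5
            fx.append(
                {
                    "peak_id": pid,
                    "contrast": contrast,
                    "direction": "open" if up else "closed",
                    "log2fc": cfg.effect_log2fc if up else -cfg.effect_log2fc,
                }
            )
    df = pd.DataFrame(fx, columns=["peak_id", "contrast", "direction", "log2fc"])
    return df.drop_duplicates(subset=["peak_id", "contrast"], keep="first")


def _gene_effects(
    cfg: SimulationConfig,
    effects: pd.DataFrame,
    annotations: pd.DataFrame,
    rng: np.random.Generator,
) -> Tuple[pd.DataFrame, pd.DataFrame]:
    """Expression effects at the closest genes of planted DARs.

    Each planted DAR's closest gene responds concordantly with probability
    ``gene_concordant_fraction``, discordantly with
    ``gene_discordant_fraction``, else not at all.  A gene already assigned
    in a contrast keeps its first assignment.  Returns (gene_effects,
    concordant_pairs).
    """
    closest = annotations.set_index("id")["closest_gene"].to_dict()
    assigned: Set[Tuple[str, str]] = set()
    gfx: List[Dict] = []
    pairs: List[Dict] = []
    for rec in effects.itertuples(index=False):
        gene = closest.get(rec.peak_id)
        if gene is None or pd.isna(gene):
            continue
        key = (rec.contrast, gene)
        if key in assigned:
            continue
        u = rng.random()
        if u < cfg.gene_concordant_fraction:
            response = "concordant"
        elif u < cfg.gene_concordant_fraction + cfg.gene_discordant_fraction:
            response = "discordant"
        else:
            continue
        assigned.add(key)
        acc_up = rec.direction == "open"
        expr_up = acc_up if response == "concordant" else not acc_up
        gfx.append(
            {
                "gene_id": gene,
                "contrast": rec.contrast,
                "direction": "up" if expr_up else "down",
                "log2fc": cfg.gene_effect_log2fc if expr_up else -cfg.gene_effect_log2fc,
            }
        )
        if response == "concordant":
            pairs.append(
                {
                    "contrast": rec.contrast,
                    "peak_id": rec.peak_id,
                    "gene_id": gene,
                    "acc_direction": rec.direction,
                    "expr_direction": "up" if expr_up else "down",
                }
            )
    return (
        pd.DataFrame(gfx, columns=["gene_id", "contrast", "direction", "log2fc"]),
        pd.DataFrame(
            pairs,
            columns=["contrast", "peak_id", "gene_id", "acc_direction", "expr_direction"],
        ),
    )


def _make_states(
    cfg: SimulationConfig,
    peaks: RegionSet,
    planted_distnc: Sequence[str],
    rng: np.random.Generator,
) -> pd.DataFrame:
    """Background state tiling plus enhancer segments over planted peaks."""
    rows = []
    bg_states = [s for s in STATE_LABELS if s not in ENHANCER_STATES]
    for c in range(cfg.n_chroms):
        chrom = f"chr{c + 1}"
        pos = 0
        while pos < cfg.chrom_length:
            ln = int(rng.integers(cfg.state_segment_length // 2, cfg.state_segment_length * 2))
            end = min(pos + ln, cfg.chrom_length)
            label = bg_states[int(rng.integers(0, len(bg_states)))]
            # sprinkle background enhancer segments at a low rate
            if rng.random() < 0.06:
                label = ENHANCER_STATES[int(rng.integers(0, 2))]
            rows.append((chrom, pos, end, label))
            pos = end
    for pid in planted_distnc:
        if rng.random() < cfg.enhancer_state_prob:
            r = peaks[pid]
            pad = int(rng.integers(50, 400))
            rows.append(
                (
                    r.chrom,
                    max(0, r.start - pad),
                    min(cfg.chrom_length, r.end + pad),
                    ENHANCER_STATES[int(rng.integers(0, 2))],
                )
            )
    return pd.DataFrame(rows, columns=["chrom", "start", "end", "state"])


def simulate_genome(cfg: Optional[SimulationConfig] = None) -> SimulatedData:
    """Genes, peaks, states, sequences and planted truth for one run."""
    cfg = cfg or SimulationConfig()
    genes = _lay_genes(cfg, cfg.rng("genes"))
    peaks = _place_peaks(cfg, genes, cfg.rng("peaks"))
    annotations = RegionAnnotator().fit(genes).transform(peaks)

    fx_rng = cfg.rng("effects")
    effects = _plant_effects(cfg, annotations, fx_rng)
    gene_fx, pairs = _gene_effects(cfg, effects, annotations, fx_rng)

    aging_closed = effects.query("contrast == 'aging' and direction == 'closed'")
    iis_open = effects.query("contrast == 'iis' and direction == 'open'")
    # the planted anti-concordant set: distNC peaks closing with age and
    # re-opening under reduced IIS (promoters may coincide by chance in the
    # two independent contrasts; those are not planted structure)
    distnc_ids = set(annotations.loc[annotations["is_distnc"], "id"])
    anti = sorted(
        (set(aging_closed["peak_id"]) & set(iis_open["peak_id"])) & distnc_ids
    )
    states = _make_states(cfg, peaks, anti, cfg.rng("states"))

    seq_rng = cfg.rng("sequences")
    motif = _random_pwm(cfg, seq_rng, "planted_motif")
    freqs = np.asarray(cfg.base_freqs)
    sequences: Dict[str, str] = {}
    opening_ids = set(iis_open["peak_id"])
    motif_regions: List[str] = []
    for r in peaks:
        seq = "".join(
            BASES[i] for i in seq_rng.choice(4, size=r.width, p=freqs)
        )
        if r.id in opening_ids and seq_rng.random() < cfg.motif_planting_fraction:
            inst = _sample_motif_instance(motif, seq_rng)
            off = int(seq_rng.integers(0, r.width - len(inst)))
            seq = seq[:off] + inst + seq[off + len(inst):]
            motif_regions.append(r.id)
        sequences[r.id] = seq

    truth = {
        "effects": effects,
        "gene_effects": gene_fx,
        "concordant_pairs": pairs,
        "anti_concordant_peaks": anti,
        "motif_regions": motif_regions,
        "iis_opening_peaks": sorted(opening_ids),
    }
    return SimulatedData(
        config=cfg,
        genes=genes,
        peaks=peaks,
        annotations=annotations,
        states=states,
        sequences=sequences,
        motif=motif,
        truth=truth,
    )


# ---------------------------------------------------------------------------
# counts
# ---------------------------------------------------------------------------

CONTRAST_GROUPS = {"aging": ("young", "old"), "iis": ("wt", "iis_mutant")}


def _nb_draw(
    rng: np.random.Generator, mean: np.ndarray, phi: float
) -> np.ndarray:
    if phi <= 0:
        return rng.poisson(mean)
    lam = rng.gamma(shape=1.0 / phi, scale=mean * phi)
    return rng.poisson(lam)


def _count_matrix(
    cfg: SimulationConfig,
    feature_ids: List[str],
    log2fc: Mapping[str, float],
    groups: Tuple[str, str],
    rng: np.random.Generator,
) -> CountMatrix:
    n = len(feature_ids)
    base = cfg.baseline_mean * np.exp(
        rng.normal(0.0, cfg.baseline_log_sd, size=n)
        - cfg.baseline_log_sd**2 / 2
    )
    fc = np.array([2.0 ** log2fc.get(f, 0.0) for f in feature_ids])
    cols = {}
    group_map = {}
    for gi, group in enumerate(groups):
        mu = base * fc if gi == 1 else base
        for rep in range(cfg.n_replicates):
            depth = float(np.exp(rng.normal(0.0, cfg.depth_log_sd)))
            name = f"{group}_{rep + 1}"
            cols[name] = _nb_draw(rng, mu * depth, cfg.nb_dispersion)
            group_map[name] = group
    counts = pd.DataFrame(cols, index=feature_ids)
    return CountMatrix(counts, group_map)


def simulate_counts(
    cfg: SimulationConfig, sim: SimulatedData
) -> Dict[str, Dict[str, CountMatrix]]:
    """Peak and gene count matrices for the aging and IIS contrasts."""
    out: Dict[str, Dict[str, CountMatrix]] = {"peaks": {}, "genes": {}}
    peak_ids = sim.peaks.ids
    gene_ids = [g.gene_id for g in sim.genes]
    for contrast, groups in CONTRAST_GROUPS.items():
        pk_fx = (
            sim.truth["effects"]
            .query("contrast == @contrast")
            .set_index("peak_id")["log2fc"]
            .to_dict()
        )
        gn_fx = (
            sim.truth["gene_effects"]
            .query("contrast == @contrast")
            .set_index("gene_id")["log2fc"]
            .to_dict()
        )
        out["peaks"][contrast] = _count_matrix(
            cfg, peak_ids, pk_fx, groups, cfg.rng(f"counts-peaks-{contrast}")
        )
        out["genes"][contrast] = _count_matrix(
            cfg, gene_ids, gn_fx, groups, cfg.rng(f"counts-genes-{contrast}")
        )
    return out


# ---------------------------------------------------------------------------
# lifespans
# ---------------------------------------------------------------------------


def simulate_lifespans(cfg: Optional[SimulationConfig] = None) -> pd.DataFrame:
    """Weibull lifespans per group with the configured target medians.

    Times are continuous days; an animal is censored (event = 0) when an
    independent uniform censoring clock, active for a ``censoring_rate``
    fraction of animals, fires before its death.
    """
    cfg = cfg or SimulationConfig()
    rng = cfg.rng("lifespans")
    rows = []
    for group in sorted(cfg.survival_medians):
        median = cfg.survival_medians[group]
        scale = median / np.log(2) ** (1.0 / cfg.weibull_shape)
        t = scale * rng.weibull(cfg.weibull_shape, size=cfg.n_per_group)
        censored = rng.random(cfg.n_per_group) < cfg.censoring_rate
        c_time = rng.uniform(0.0, 1.5 * median, size=cfg.n_per_group)
        obs = np.where(censored & (c_time < t), c_time, t)
        event = np.where(censored & (c_time < t), 0, 1)
        obs = np.maximum(obs, 1e-3)
        for ti, ei in zip(obs, event):
            rows.append({"time": float(ti), "event": int(ei), "group": group})
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# run directory
# ---------------------------------------------------------------------------


def write_run_dir(
    sim: SimulatedData,
    counts: Dict[str, Dict[str, CountMatrix]],
    lifespans: pd.DataFrame,
    outdir,
) -> Path:
    """Write every simulated input in its standard on-disk format."""
    out = Path(outdir)
    out.mkdir(parents=True, exist_ok=True)
    tio.write_gff3(sim.genes, out / "genes.gff3")
    tio.write_bed(sim.peaks, out / "peaks.bed")
    tio.write_state_bed(sim.states, out / "states.bed")
    tio.write_fasta(sim.sequences, out / "peak_sequences.fa")
    write_homer_motifs([sim.motif], out / "motifs.motif")
    meta = {"seed": sim.config.seed}
    for kind, per_contrast in counts.items():
        for contrast, cm in per_contrast.items():
            tio.write_counts(
                cm.counts, out / f"counts_{kind}_{contrast}.tsv", meta
            )
            (out / f"groups_{kind}_{contrast}.json").write_text(
                json.dumps(cm.sample_groups, indent=1)
            )
    tio.write_survival_csv(lifespans, out / "lifespans.csv")
    truth = {
        k: (v.to_dict(orient="records") if isinstance(v, pd.DataFrame) else v)
        for k, v in sim.truth.items()
    }
    (out / "truth.json").write_text(json.dumps(truth, indent=1))
    tio.write_table(sim.annotations, out / "annotations.tsv", meta)
    return out
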