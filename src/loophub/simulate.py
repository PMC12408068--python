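"""Truth-labelled synthetic dataset generator.

Generates a small genome with genes, per-condition peak sets, a loop list
with replicate PET counts and FDRs, speckle-like binned signal tracks, a
distance-decay contact matrix with planted loop-pixel enrichment, and an
expression table with four planted archetypes — together with truth tables
recording every planted label, so the downstream analyses can be tested
without external data.

Randomness is split into named per-component streams derived from a single
integer seed, so components can be regenerated independently and outputs
are byte-identical for a fixed seed.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field, asdict
from pathlib import Path
from typing import Dict, List, Optional, Sequence, Tuple

import numpy as np
import pandas as pd

from .core.intervals import Genome, GenomicInterval, IntervalIndex
from .core.tracks import SignalTrack, map_binned_signal
from .core.matrix import ContactMatrix
from .core.genes import Gene, GeneModel, write_gff3
from .core.loops import Loop
from .core import io as core_io

_STREAMS = {
    "genes": 1,
    "track": 2,
    "peaks": 3,
    "loops": 4,
    "matrix": 5,
    "expression": 6,
    "blacklist": 7,
    "archetypes": 8,
}


def component_rng(seed: int, component: str) -> np.random.Generator:
    """Named per-component random stream derived from the master seed."""
    return np.random.default_rng(
        np.random.SeedSequence(entropy=seed, spawn_key=(_STREAMS[component],))
    )


class PlacementError(RuntimeError):
    """Raised when the genome is too small for the requested feature count."""


@dataclass
class SimulationConfig:
    seed: int = 0
    n_chrom: int = 2
    chrom_length: int = 20_000_000
    matrix_bin: int = 10_000
    signal_bin: int = 20_000
    n_genes: int = 400
    n_constitutive_peaks: int = 800
    n_condition_specific_peaks: int = 150
    n_hubs: int = 40
    hub_partner_range: Tuple[int, int] = (8, 25)
    nonhub_partner_range: Tuple[int, int] = (0, 3)
    loop_distance_range: Tuple[int, int] = (50_000, 2_000_000)
    pet_mean: float = 30.0
    pet_dispersion: float = 0.2
    delta_logfc: float = 0.3
    speckle_gain: float = 3.0
    loop_pixel_enrichment: float = 3.0
    n_replicates: int = 2
    n_decoy_loops: int = 100
    archetype_noise_sd: float = 0.3
    # planted expression class sizes (flat genes make up the remainder)
    archetype_sizes: Tuple[int, int, int, int] = (33, 48, 6, 54)
    # condition-specific placement fractions: non-intronic gene body,
    # intronic, intergenic
    specific_placement: Tuple[float, float, float] = (0.5, 0.3, 0.2)
    # loop strength scales with anchor speckle signal:
    # factor = strength_base + strength_slope * log2(1 + signal)
    strength_base: float = 0.55
    strength_slope: float = 1.0
    # fraction of condition-specific peaks that anchor a loop, and their
    # baseline strength multiplier
    specific_loop_fraction: float = 0.4
    specific_pet_scale: float = 0.9
    speckle_bump_amplitude: float = 4.0
    speckle_baseline_sigma: float = 0.5
    matrix_noise_sd: float = 0.1
    expression_effect: float = 1.0
    n_blacklist: int = 5

    def __post_init__(self) -> None:
        for name in (
            "n_chrom", "chrom_length", "matrix_bin", "signal_bin", "n_genes",
            "n_constitutive_peaks", "n_replicates",
        ):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")
        if self.n_hubs < 0 or self.n_condition_specific_peaks < 0:
            raise ValueError("feature counts must be non-negative")
        for name in ("hub_partner_range", "nonhub_partner_range", "loop_distance_range"):
            lo, hi = getattr(self, name)
            if lo > hi:
                raise ValueError(f"{name} must be ordered, got ({lo}, {hi})")
        if sum(self.archetype_sizes) > self.n_genes:
            raise ValueError("archetype sizes exceed n_genes")
        if abs(sum(self.specific_placement) - 1.0) > 1e-9:
            raise ValueError("specific_placement fractions must sum to 1")

    # Flat key=value config file ------------------------------------------------
    def to_file(self, path) -> None:
        with open(path, "w") as fh:
            for key, value in asdict(self).items():
                if isinstance(value, (tuple, list)):
                    value = ",".join(str(v) for v in value)
                fh.write(f"{key} = {value}\n")

    @classmethod
    def from_file(cls, path) -> "SimulationConfig":
        kwargs = {}
        defaults = cls()
        for lineno, line in enumerate(open(path), 1):
            line = line.strip()
            if not line or line.startswith("#"):
                continue
            if "=" not in line:
                raise ValueError(f"{path}:{lineno}: expected 'key = value'")
            key, value = (part.strip() for part in line.split("=", 1))
            if not hasattr(defaults, key):
                raise ValueError(f"{path}:{lineno}: unknown config key {key!r}")
            default = getattr(defaults, key)
            if isinstance(default, tuple):
                elem = type(default[0])
                kwargs[key] = tuple(elem(float(v)) if elem is int else elem(v)
                                    for v in value.split(","))
            elif isinstance(default, bool):
                kwargs[key] = value.lower() in ("1", "true", "yes")
            elif isinstance(default, int):
                kwargs[key] = int(float(value))
            elif isinstance(default, float):
                kwargs[key] = float(value)
            else:
                kwargs[key] = value
        return cls(**kwargs)


@dataclass
class TruthTables:
    """Planted labels: the acceptance surface of the generator."""

    hub_ids: List[str] = field(default_factory=list)
    specific_ids: List[str] = field(default_factory=list)
    specific_categories: Dict[str, str] = field(default_factory=dict)
    strengthened_loop_ids: List[str] = field(default_factory=list)
    decoy_loop_ids: List[str] = field(default_factory=list)
    speckle_center_bins: List[Tuple[str, int]] = field(default_factory=list)
    archetypes: Dict[str, int] = field(default_factory=dict)  # gene -> 0..4 (0 flat)

    def to_json(self, path) -> None:
        obj = asdict(self)
        obj["speckle_center_bins"] = [[c, int(b)] for c, b in self.speckle_center_bins]
        with open(path, "w") as fh:
            json.dump(obj, fh, indent=1, sort_keys=True)

    @classmethod
    def from_json(cls, path) -> "TruthTables":
        with open(path) as fh:
            obj = json.load(fh)
        obj["speckle_center_bins"] = [tuple(x) for x in obj["speckle_center_bins"]]
        return cls(**obj)


@dataclass
class SyntheticDataset:
    config: SimulationConfig
    genome: Genome
    genes: GeneModel
    # peak tables: one row per peak with planted metadata
    peaks: pd.DataFrame
    loops: List[Loop]
    tracks: Dict[str, SignalTrack]  # condition -> track
    matrices: Dict[str, ContactMatrix]  # chrom -> matrix (may be empty)
    expression: pd.DataFrame
    blacklist: List[GenomicInterval]
    truth: TruthTables

    def peak_intervals(self, condition: Optional[str] = None) -> List[GenomicInterval]:
        df = self.peaks
        if condition is not None:
            df = df[df[f"called_{condition}"]]
        return [
            GenomicInterval(r.chrom, r.start, r.end, r.strand, r.id, r.signal)
            for r in df.itertuples()
        ]


# ---------------------------------------------------------------------------
# Genome and genes

def _make_genome(config: SimulationConfig) -> Genome:
    return Genome({f"chr{i + 1}": config.chrom_length for i in range(config.n_chrom)})


def simulate_genes(config: SimulationConfig, genome: Genome) -> GeneModel:
    """Evenly spaced, jittered, non-overlapping genes with 3-6 exons each."""
    rng = component_rng(config.seed, "genes")
    chroms = genome.chroms
    per_chrom = [config.n_genes // len(chroms)] * len(chroms)
    for i in range(config.n_genes - sum(per_chrom)):
        per_chrom[i] += 1
    genes: List[Gene] = []
    gid = 0
    for chrom, n in zip(chroms, per_chrom):
        slot = genome.length(chrom) / (n + 1)
        if slot < 70_000:
            raise PlacementError(f"too many genes for {chrom}")
        for k in range(n):
            length = int(rng.uniform(20_000, min(60_000, slot * 0.8)))
            center = (k + 1) * slot + rng.uniform(-0.1, 0.1) * slot
            start = int(center - length / 2)
            start = max(2_000, min(start, genome.length(chrom) - length - 2_000))
            strand = "+" if rng.random() < 0.5 else "-"
            gid += 1
            iv = GenomicInterval(chrom, start, start + length, strand, f"G{gid:04d}")
            n_exons = int(rng.integers(3, 7))
            # 2*n_exons - 1 alternating exon/intron segments spanning the gene
            weights = rng.dirichlet(np.ones(2 * n_exons - 1) * 2.0)
            bounds = np.concatenate([[0], np.cumsum(weights)]) * length
            exons = []
            for e in range(n_exons):
                s = start + int(bounds[2 * e])
                t = start + int(bounds[2 * e + 1])
                if t - s >= 50:
                    exons.append(GenomicInterval(chrom, s, t, strand))
            genes.append(Gene(iv, exons))
    return GeneModel(genes)


# ---------------------------------------------------------------------------
# Speckle track

def simulate_speckle_track(
    config: SimulationConfig,
    genome: Genome,
    center_bins: Sequence[Tuple[str, int]],
    bump_amplitude: Optional[float] = None,
) -> SignalTrack:
    """Lognormal baseline plus Gaussian bumps at speckle-center bins.

    This is the condition-A (baseline) track; the condition-B track is
    derived later by multiplying bins containing condition-specific peaks
    by ``speckle_gain``.
    """
    rng = component_rng(config.seed, "track")
    amp = config.speckle_bump_amplitude if bump_amplitude is None else bump_amplitude
    track = SignalTrack.zeros(genome, config.signal_bin)
    for chrom in genome.chroms:
        n = genome.n_bins(chrom, config.signal_bin)
        track.values[chrom] = rng.lognormal(
            mean=0.0, sigma=config.speckle_baseline_sigma, size=n
        )
    sigma_bins = 0.8
    for chrom, b in center_bins:
        n = len(track.values[chrom])
        lo, hi = max(0, b - 5), min(n, b + 6)
        offsets = np.arange(lo, hi) - b
        track.values[chrom][lo:hi] += amp * np.exp(
            -(offsets ** 2) / (2 * sigma_bins ** 2)
        )
    return track


def apply_condition_gain(
    config: SimulationConfig,
    track: SignalTrack,
    specific_peaks: Sequence[GenomicInterval],
) -> SignalTrack:
    """Condition-B track: gain over bins containing condition-specific peaks."""
    out = track.copy()
    for iv in specific_peaks:
        for b in out.bin_range(iv.chrom, iv.start, iv.end):
            out.values[iv.chrom][b] = track.values[iv.chrom][b] * config.speckle_gain
    return out


# ---------------------------------------------------------------------------
# Peaks and loops

def _place_nonoverlapping(
    rng: np.random.Generator,
    genome: Genome,
    n: int,
    width_range: Tuple[int, int],
    occupied: Dict[str, List[Tuple[int, int]]],
    position_sampler,
    max_tries_factor: int = 200,
) -> List[GenomicInterval]:
    """Rejection-sample ``n`` intervals that avoid ``occupied`` (updated in place)."""
    placed: List[GenomicInterval] = []
    tries = 0
    max_tries = max_tries_factor * max(n, 1)
    while len(placed) < n:
        tries += 1
        if tries > max_tries:
            raise PlacementError(
                f"could not place {n} features (placed {len(placed)}); "
                "genome too small or constraints too tight"
            )
        chrom, pos = position_sampler()
        width = int(rng.integers(width_range[0], width_range[1] + 1))
        start = int(pos - width // 2)
        end = start + width
        if start < 0 or end > genome.length(chrom):
            continue
        clash = any(s < end and e > start for s, e in occupied.setdefault(chrom, []))
        if clash:
            continue
        occupied[chrom].append((start, end))
        placed.append(GenomicInterval(chrom, start, end))
    return placed


def _negbin(rng: np.random.Generator, mean: float, dispersion: float, size) -> np.ndarray:
    """Negative binomial with var = mean + dispersion * mean^2 (Poisson if 0)."""
    if dispersion <= 0 or mean <= 0:
        return rng.poisson(max(mean, 0), size=size)
    r = 1.0 / dispersion
    p = r / (r + mean)
    return rng.negative_binomial(r, p, size=size)


def simulate_peaks_and_loops(
    config: SimulationConfig,
    genome: Genome,
    genes: GeneModel,
    track: SignalTrack,
    arch2_gene_ids: Sequence[str],
    center_bins: Sequence[Tuple[str, int]],
) -> Tuple[pd.DataFrame, List[Loop], TruthTables]:
    """Place constitutive/hub/condition-specific peaks and wire the loop list.

    Hubs are placed in speckle-bump (top-decile signal) bins and wired to
    8-25 non-hub partners; non-hubs carry at most their sampled partner
    quota; condition-specific peaks appear only in the condition-B peak set,
    sit preferentially on non-intronic gene bodies of the speckle-proximal
    expression archetype, and anchor one loop each to a nearby hub whose
    strength is multiplied by ``2**delta_logfc`` in condition-B samples.
    """
    rng = component_rng(config.seed, "peaks")
    lrng = component_rng(config.seed, "loops")
    truth = TruthTables()
    occupied: Dict[str, List[Tuple[int, int]]] = {}
    gene_by_id = genes.by_id()
    width_range = (300, 600)

    # --- hubs near speckle centers (top-decile signal bins by construction)
    if not center_bins and config.n_hubs > 0:
        raise PlacementError("hubs requested but no speckle centers available")

    def hub_pos():
        # entirely inside a speckle-center bin, so hub signal is the full
        # bump amplitude (top-decile by construction)
        chrom, b = center_bins[int(rng.integers(len(center_bins)))]
        offset = rng.uniform(400, config.signal_bin - 400)
        return chrom, int(b * config.signal_bin + offset)

    hub_ivs = _place_nonoverlapping(
        rng, genome, config.n_hubs, width_range, occupied, hub_pos
    )

    # --- remaining constitutive peaks anywhere
    def any_pos():
        chrom = genome.chroms[int(rng.integers(len(genome.chroms)))]
        return chrom, int(rng.uniform(1_000, genome.length(chrom) - 1_000))

    n_rest = config.n_constitutive_peaks - config.n_hubs
    if n_rest < 0:
        raise ValueError("n_hubs exceeds n_constitutive_peaks")
    rest_ivs = _place_nonoverlapping(
        rng, genome, n_rest, width_range, occupied, any_pos
    )

    # --- condition-specific peaks on archetype-2 gene bodies / intergenic
    n_spec = config.n_condition_specific_peaks
    f_exonic, f_intronic, _ = config.specific_placement
    n_exonic = int(round(n_spec * f_exonic))
    n_intronic = int(round(n_spec * f_intronic))
    n_intergenic = n_spec - n_exonic - n_intronic
    arch2_genes = [gene_by_id[g] for g in arch2_gene_ids] or list(genes.genes)

    hub_index = IntervalIndex(hub_ivs)
    lo_d, hi_d = config.loop_distance_range

    def has_hub_in_range(chrom: str, pos: int) -> bool:
        hits = hub_index.query(chrom, max(0, pos - hi_d), pos + hi_d)
        for h in hits:
            d = abs(hub_ivs[h].center - pos)
            if lo_d <= d <= hi_d:
                return True
        return False

    def exonic_pos():
        g = arch2_genes[int(rng.integers(len(arch2_genes)))]
        exons = [e for e in g.exons if len(e) >= 800]
        if not exons:
            exons = g.exons
        ex = exons[int(rng.integers(len(exons)))]
        pad = min(len(ex) // 4, 300)
        pos = int(rng.uniform(ex.start + pad, ex.end - pad))
        # keep away from promoter/TTS windows so annotation truth is clean
        if g.promoter().start - 700 <= pos <= g.promoter().end + 700:
            return ex.chrom, -1
        if g.tts_window().start - 700 <= pos <= g.tts_window().end + 700:
            return ex.chrom, -1
        if not has_hub_in_range(ex.chrom, pos):
            return ex.chrom, -1
        return ex.chrom, pos

    def intronic_pos():
        g = arch2_genes[int(rng.integers(len(arch2_genes)))]
        iv = g.interval
        introns = []
        prev = iv.start
        for ex in g.exons:
            if ex.start - prev >= 1500:
                introns.append((prev, ex.start))
            prev = ex.end
        if iv.end - prev >= 1500:
            introns.append((prev, iv.end))
        if not introns:
            return iv.chrom, -1
        s, e = introns[int(rng.integers(len(introns)))]
        pos = int(rng.uniform(s + 400, e - 400))
        if g.promoter().start - 700 <= pos <= g.promoter().end + 700:
            return iv.chrom, -1
        if g.tts_window().start - 700 <= pos <= g.tts_window().end + 700:
            return iv.chrom, -1
        if not has_hub_in_range(iv.chrom, pos):
            return iv.chrom, -1
        return iv.chrom, pos

    gene_index = IntervalIndex([g.interval for g in genes.genes])

    def intergenic_pos():
        chrom, b = center_bins[int(rng.integers(len(center_bins)))]
        pos = int(b * config.signal_bin + rng.uniform(-5, 5) * config.signal_bin)
        pos = max(2_000, min(pos, genome.length(chrom) - 2_000))
        if gene_index.query(chrom, pos - 1_200, pos + 1_200):
            return chrom, -1
        if not has_hub_in_range(chrom, pos):
            return chrom, -1
        return chrom, pos

    def guarded(sampler):
        def inner():
            chrom, pos = sampler()
            return (chrom, pos) if pos >= 0 else (chrom, -10)  # rejected below
        return inner

    def place_spec(n, sampler, category):
        ivs = _place_nonoverlapping(
            rng, genome, n, width_range, occupied, guarded(sampler),
            max_tries_factor=2000,
        )
        return [(iv, category) for iv in ivs]

    spec_placed = []
    if n_spec:
        if not center_bins:
            raise PlacementError("condition-specific peaks need speckle centers")
        spec_placed += place_spec(n_exonic, exonic_pos, "non_intronic_gene_body")
        spec_placed += place_spec(n_intronic, intronic_pos, "intronic")
        spec_placed += place_spec(n_intergenic, intergenic_pos, "intergenic")

    # --- assemble the peak table
    records = []
    hub_ids, spec_ids = [], []
    counter = 0

    def add_peak(iv: GenomicInterval, is_hub: bool, specific: bool, category: str = ""):
        nonlocal counter
        counter += 1
        pid = f"P{counter:05d}"
        strand = "+" if rng.random() < 0.5 else "-"
        signal = float(rng.lognormal(2.0, 0.5))
        if specific:
            logfc = float(rng.normal(2.0, 0.3))
        else:
            logfc = float(rng.normal(0.0, 0.1))
        records.append(
            dict(
                id=pid, chrom=iv.chrom, start=iv.start, end=iv.end,
                strand=strand, signal=signal, chip_logfc=logfc,
                called_A=not specific, called_B=True,
            )
        )
        if is_hub:
            hub_ids.append(pid)
        if specific:
            spec_ids.append(pid)
            truth.specific_categories[pid] = category
        return pid

    hub_pids = [add_peak(iv, True, False) for iv in hub_ivs]
    nonhub_pids = [add_peak(iv, False, False) for iv in rest_ivs]
    spec_pids = [add_peak(iv, False, True, cat) for iv, cat in spec_placed]
    truth.hub_ids = hub_ids
    truth.specific_ids = spec_ids

    peaks = pd.DataFrame.from_records(records)
    by_id = {r["id"]: GenomicInterval(r["chrom"], r["start"], r["end"])
             for r in records}

    # --- wire loops
    samples = [
        f"{cond}:{rep + 1}"
        for cond in ("A", "B")
        for rep in range(config.n_replicates)
    ]
    loops: List[Loop] = []
    seen_pairs = set()

    def anchor_signal(pid: str) -> float:
        iv = by_id[pid]
        b = iv.center // config.signal_bin
        return float(track.values[iv.chrom][b])

    def strength_factor(pid1: str, pid2: str) -> float:
        sig = 0.5 * (anchor_signal(pid1) + anchor_signal(pid2))
        return config.strength_base + config.strength_slope * np.log2(1.0 + sig)

    def add_loop(pid1: str, pid2: str, mean_a: float, mean_b: float,
                 fdr: float, prefix: str) -> Optional[str]:
        key = tuple(sorted((pid1, pid2)))
        if key in seen_pairs:
            return None
        seen_pairs.add(key)
        lid = f"{prefix}{len(loops) + 1:05d}"
        pets = {}
        for s in samples:
            mean = mean_a if s.startswith("A") else mean_b
            pets[s] = int(_negbin(lrng, mean, config.pet_dispersion, None))
        loops.append(Loop(lid, by_id[pid1], by_id[pid2], pets, fdr))
        return lid

    # hub -> non-hub wiring under per-non-hub capacity
    nonhub_capacity = {
        pid: int(lrng.integers(config.nonhub_partner_range[0],
                               config.nonhub_partner_range[1] + 1))
        for pid in nonhub_pids
    }
    nonhub_index = IntervalIndex([by_id[p] for p in nonhub_pids])

    def eligible_nonhubs(center_iv: GenomicInterval) -> List[str]:
        pos = center_iv.center
        hits = nonhub_index.query(center_iv.chrom, max(0, pos - hi_d), pos + hi_d)
        out = []
        for h in hits:
            pid = nonhub_pids[h]
            d = abs(by_id[pid].center - pos)
            if lo_d <= d <= hi_d and nonhub_capacity[pid] > 0:
                out.append(pid)
        return out

    nonhub_counts = {pid: 0 for pid in nonhub_pids}
    for hub in hub_pids:
        quota = int(lrng.integers(config.hub_partner_range[0],
                                  config.hub_partner_range[1] + 1))
        partners = eligible_nonhubs(by_id[hub])
        lrng.shuffle(partners)
        if len(partners) < quota:
            # capacity exhausted nearby: overflow the least-loaded in-window
            # non-hubs so the hub truth label stays honest
            pos = by_id[hub].center
            hits = nonhub_index.query(
                by_id[hub].chrom, max(0, pos - hi_d), pos + hi_d
            )
            extra = []
            for h in hits:
                pid = nonhub_pids[h]
                d = abs(by_id[pid].center - pos)
                if lo_d <= d <= hi_d and pid not in partners:
                    extra.append(pid)
            extra.sort(key=lambda p: (nonhub_counts[p], p))
            partners += extra
        for pid in partners[:quota]:
            fdr = float(lrng.uniform(0, 0.005))
            mean = config.pet_mean * strength_factor(hub, pid)
            if add_loop(hub, pid, mean, mean, fdr, "L"):
                nonhub_capacity[pid] -= 1
                nonhub_counts[pid] += 1

    # non-hub <-> non-hub pairing for the remaining capacity
    remaining = [p for p in nonhub_pids if nonhub_capacity[p] > 0]
    lrng.shuffle(remaining)
    for pid in remaining:
        while nonhub_capacity[pid] > 0:
            pos = by_id[pid].center
            hits = nonhub_index.query(by_id[pid].chrom, max(0, pos - hi_d), pos + hi_d)
            cands = []
            for h in hits:
                q = nonhub_pids[h]
                if q == pid or nonhub_capacity[q] <= 0:
                    continue
                d = abs(by_id[q].center - pos)
                if lo_d <= d <= hi_d:
                    cands.append(q)
            if not cands:
                break
            q = cands[int(lrng.integers(len(cands)))]
            fdr = float(lrng.uniform(0, 0.005))
            mean = config.pet_mean * strength_factor(pid, q)
            if add_loop(pid, q, mean, mean, fdr, "L"):
                nonhub_capacity[pid] -= 1
                nonhub_capacity[q] -= 1
            else:
                break

    # a fraction of condition-specific peaks anchor one strengthened loop
    # each, to a nearby hub
    strengthened = []
    gain = 2.0 ** config.delta_logfc
    n_looping_spec = int(round(len(spec_pids) * config.specific_loop_fraction))
    looping_spec = list(spec_pids)
    lrng.shuffle(looping_spec)
    for pid in looping_spec[:n_looping_spec]:
        pos = by_id[pid].center
        hits = hub_index.query(by_id[pid].chrom, max(0, pos - hi_d), pos + hi_d)
        cands = []
        for h in hits:
            d = abs(hub_ivs[h].center - pos)
            if lo_d <= d <= hi_d:
                cands.append(hub_pids[h])
        if not cands:
            warnings.warn(f"no hub in loop range for specific peak {pid}")
            continue
        hub = cands[int(lrng.integers(len(cands)))]
        base = (
            config.pet_mean * config.specific_pet_scale * strength_factor(pid, hub)
        )
        fdr = float(lrng.uniform(0, 0.005))
        lid = add_loop(pid, hub, base, base * gain, fdr, "S")
        if lid and config.delta_logfc != 0:
            strengthened.append(lid)
    truth.strengthened_loop_ids = strengthened

    # decoys: high FDR, low PETs
    all_pids = hub_pids + nonhub_pids + spec_pids
    decoys = []
    tries = 0
    while len(decoys) < config.n_decoy_loops and tries < 200 * max(config.n_decoy_loops, 1):
        tries += 1
        p1 = all_pids[int(lrng.integers(len(all_pids)))]
        p2 = all_pids[int(lrng.integers(len(all_pids)))]
        if p1 == p2 or by_id[p1].chrom != by_id[p2].chrom:
            continue
        d = abs(by_id[p1].center - by_id[p2].center)
        if not lo_d <= d <= hi_d:
            continue
        fdr = float(lrng.uniform(0.05, 1.0))
        lid = add_loop(p1, p2, 2.0, 2.0, fdr, "D")
        if lid:
            decoys.append(lid)
    truth.decoy_loop_ids = decoys

    return peaks, loops, truth


# ---------------------------------------------------------------------------
# Contact matrix

def simulate_contact_matrix(
    config: SimulationConfig,
    genome: Genome,
    loops: Sequence[Loop],
    decoy_ids: Sequence[str] = (),
) -> Dict[str, ContactMatrix]:
    """Distance-decay matrices with multiplicative loop-pixel enrichment.

    Expected decay is ``1 / (1 + s)`` in bins; each true loop's anchor-pair
    pixel is multiplied by ``loop_pixel_enrichment`` (half effect on the
    1-pixel neighborhood), multiplicative lognormal noise is applied, and
    the diagonal is set to missing.
    """
    rng = component_rng(config.seed, "matrix")
    decoy = set(decoy_ids)
    bs = config.matrix_bin
    out: Dict[str, ContactMatrix] = {}
    for chrom in genome.chroms:
        n = genome.n_bins(chrom, bs)
        s = np.abs(np.subtract.outer(np.arange(n), np.arange(n)))
        mat = 1.0 / (1.0 + s)
        enrich = np.ones((n, n))
        e = config.loop_pixel_enrichment
        half = 1.0 + (e - 1.0) / 2.0
        for lp in loops:
            if lp.chrom != chrom or lp.id in decoy:
                continue
            i = lp.anchor1.center // bs
            j = lp.anchor2.center // bs
            for di in (-1, 0, 1):
                for dj in (-1, 0, 1):
                    ii, jj = i + di, j + dj
                    if 0 <= ii < n and 0 <= jj < n:
                        factor = e if (di == 0 and dj == 0) else half
                        enrich[ii, jj] = max(enrich[ii, jj], factor)
                        enrich[jj, ii] = enrich[ii, jj]
        mat *= enrich
        if config.matrix_noise_sd > 0:
            noise = rng.lognormal(0.0, config.matrix_noise_sd, size=(n, n))
            upper = np.triu(noise, 1)
            noise = upper + upper.T + np.diag(np.diag(noise))
            mat *= noise
        np.fill_diagonal(mat, np.nan)
        out[chrom] = ContactMatrix(chrom, bs, mat)
    return out


# ---------------------------------------------------------------------------
# Expression

ARCHETYPE_PATTERNS = {
    # condition means in (A_ctrl, B_ctrl, A_dep, B_dep) order; "dep" is the
    # perturbation arm (factor depletion)
    1: (0.0, 1.0, 1.0, 1.0),   # up in B; also up under perturbation alone
    2: (0.0, 1.0, 0.0, 0.0),   # up in B only with the factor intact
    3: (0.0, -1.0, 0.0, -1.0),  # down in B
    4: (0.0, 1.0, 0.0, 1.0),   # up in B regardless of perturbation
}


def expression_samples(config: SimulationConfig) -> List[str]:
    return [
        f"{cond}_{arm}_r{rep + 1}"
        for arm in ("ctrl", "dep")
        for cond in ("A", "B")
        for rep in range(config.n_replicates)
    ]


def simulate_expression(
    config: SimulationConfig,
    genes: GeneModel,
    truth: TruthTables,
) -> pd.DataFrame:
    """Expression table with four planted archetype patterns plus noise.

    Emits per-sample rlog-like abundances and differential statistics
    (log2 fold-change and adjusted p for the B-vs-A contrast in the control
    arm) consistent with the planted effects.
    """
    rng = component_rng(config.seed, "expression")
    samples = expression_samples(config)
    rows = []
    for g in genes.genes:
        gid = g.interval.name
        arch = truth.archetypes.get(gid, 0)
        base = float(rng.normal(5.0, 1.0))
        values = {}
        for s in samples:
            cond, arm, _ = s.split("_")
            idx = {"A_ctrl": 0, "B_ctrl": 1, "A_dep": 2, "B_dep": 3}[f"{cond}_{arm}"]
            mean = base
            if arch:
                mean += ARCHETYPE_PATTERNS[arch][idx] * config.expression_effect
            values[s] = float(mean + rng.normal(0.0, config.archetype_noise_sd))
        if arch:
            lfc = ARCHETYPE_PATTERNS[arch][1] * config.expression_effect
            padj = float(10 ** rng.uniform(-8.0, -3.0))
        else:
            lfc = float(rng.normal(0.0, 0.05))
            padj = float(rng.uniform(0.2, 1.0))
        rows.append(
            dict(
                gene_id=gid, chrom=g.interval.chrom, start=g.interval.start,
                end=g.interval.end, strand=g.strand, **values,
                log2fc_B_vs_A=lfc, padj_B_vs_A=padj,
            )
        )
    return pd.DataFrame.from_records(rows)


# ---------------------------------------------------------------------------
# Orchestration

def simulate_dataset(config: SimulationConfig, with_matrix: bool = True) -> SyntheticDataset:
    genome = _make_genome(config)
    genes = simulate_genes(config, genome)

    # archetype assignment; archetype-2 genes host speckle centers, so they
    # are both speckle-proximal and the target of condition-specific peaks
    arng = component_rng(config.seed, "archetypes")
    order = list(range(len(genes.genes)))
    arng.shuffle(order)
    truth_arch: Dict[str, int] = {}
    offset = 0
    arch_gene_ids: Dict[int, List[str]] = {k: [] for k in (1, 2, 3, 4)}
    for arch, size in zip((1, 2, 3, 4), config.archetype_sizes):
        for i in order[offset : offset + size]:
            gid = genes.genes[i].interval.name
            truth_arch[gid] = arch
            arch_gene_ids[arch].append(gid)
        offset += size
    for i in order[offset:]:
        truth_arch[genes.genes[i].interval.name] = 0

    gene_by_id = genes.by_id()
    center_bins = []
    for gid in arch_gene_ids[2]:
        g = gene_by_id[gid]
        center_bins.append((g.interval.chrom, g.interval.center // config.signal_bin))
    center_bins = sorted(set(center_bins))

    track_a = simulate_speckle_track(config, genome, center_bins)
    peaks, loops, truth = simulate_peaks_and_loops(
        config, genome, genes, track_a, arch_gene_ids[2], center_bins
    )
    truth.archetypes = truth_arch
    truth.speckle_center_bins = center_bins

    spec_ivs = [
        GenomicInterval(r.chrom, r.start, r.end)
        for r in peaks[peaks.id.isin(truth.specific_ids)].itertuples()
    ]
    track_b = apply_condition_gain(config, track_a, spec_ivs)

    matrices = (
        simulate_contact_matrix(config, genome, loops, truth.decoy_loop_ids)
        if with_matrix
        else {}
    )
    expression = simulate_expression(config, genes, truth)

    brng = component_rng(config.seed, "blacklist")
    blacklist = []
    for k in range(config.n_blacklist):
        chrom = genome.chroms[int(brng.integers(len(genome.chroms)))]
        length = int(brng.uniform(10_000, 50_000))
        start = int(brng.uniform(0, genome.length(chrom) - length))
        blacklist.append(GenomicInterval(chrom, start, start + length, ".", f"BL{k + 1}"))

    return SyntheticDataset(
        config=config, genome=genome, genes=genes, peaks=peaks, loops=loops,
        tracks={"A": track_a, "B": track_b}, matrices=matrices,
        expression=expression, blacklist=blacklist, truth=truth,
    )


def write_dataset(ds: SyntheticDataset, outdir) -> None:
    """Write the dataset in the documented on-disk layout."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    config = ds.config
    config.to_file(outdir / "config.txt")
    with open(outdir / "genome.txt", "w") as fh:
        for chrom in ds.genome.chroms:
            fh.write(f"{chrom}\t{ds.genome.length(chrom)}\n")
    for cond in ("A", "B"):
        ivs = ds.peak_intervals(cond)
        for rep in range(config.n_replicates):
            core_io.write_bed(outdir / f"peaks_{cond}_{rep + 1}.bed", ivs)
    core_io.write_bedpe(outdir / "loops.bedpe", ds.loops)
    for cond, track in ds.tracks.items():
        core_io.write_bedgraph(outdir / f"son_{cond}.bedgraph", track)
    for chrom, mat in ds.matrices.items():
        core_io.write_matrix(outdir / f"matrix_{chrom}.tsv.gz", mat)
    write_gff3(outdir / "genes.gff3", ds.genes)
    ds.expression.to_csv(outdir / "expression.tsv", sep="\t", index=False)
    core_io.write_bed(outdir / "blacklist.bed", ds.blacklist)
    ds.truth.to_json(outdir / "truth.json")
    ds.peaks.to_csv(outdir / "peaks_meta.tsv", sep="\t", index=False)


def read_genome(path) -> Genome:
    lengths = {}
    for line in open(path):
        if line.strip():
            chrom, length = line.split("\t")
            lengths[chrom] = int(length)
    return Genome(lengths)
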