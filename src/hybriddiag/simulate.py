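"""Synthetic data generation for the hybrid-diagnosis pipeline.

Everything the downstream modules consume — diverged parental lineages,
pedigreed diploids (P1/P2/F1/F2/backcrosses), sequencing pileups, phased
haplotype blocks and citizen-science checklist tables — can be simulated
here with known ground truth, so that parameter-recovery tests have an
exact oracle.

Coordinates are 0-based, half-open throughout; conversion to 1-based
conventions happens only at I/O boundaries (see :mod:`hybriddiag.io`).
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

__all__ = [
    "ParentalPanel",
    "DiploidIndividual",
    "Pileup",
    "ChecklistTable",
    "PEDIGREE_CLASSES",
    "simulate_species_pair",
    "simulate_cross",
    "simulate_pileup",
    "simulate_phase_blocks",
    "simulate_checklists",
    "genotypes_at",
]

BASES = np.frombuffer(b"ACGT", dtype=np.uint8)
PEDIGREE_CLASSES = ("P1", "P2", "F1", "F2", "BC1P1", "BC1P2")

_EARTH_EXTENT = (-105.0, -93.0, 20.0, 35.0)  # lon_min, lon_max, lat_min, lat_max


def _seq_to_array(seq: str) -> np.ndarray:
    return np.frombuffer(seq.encode("ascii"), dtype=np.uint8).copy()


def _array_to_seq(arr: np.ndarray) -> str:
    return arr.tobytes().decode("ascii")


# ---------------------------------------------------------------------------
# Domain types
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class ParentalPanel:
    """Two labeled haploid reference lineages plus the fixed-difference truth table.

    ``seq_a`` and ``seq_b`` are the per-lineage haploid reference sequences
    (equal length ``L``); ``fixed_sites`` lists positions where the lineages
    carry distinct alleles; ``polymorphism`` records, per lineage, the
    segregating sites with their alternate allele and minor-allele frequency.
    A short maternally inherited mitochondrial replicon accompanies each
    lineage.
    """

    label_a: str
    label_b: str
    seq_a: str
    seq_b: str
    fixed_sites: np.ndarray
    polymorphism: Mapping[str, Mapping[int, tuple[str, float]]]
    mito_a: str = ""
    mito_b: str = ""

    def __post_init__(self) -> None:
        if len(self.seq_a) != len(self.seq_b):
            raise ValueError("lineage sequences must have equal length")
        if self.label_a == self.label_b:
            raise ValueError("lineage labels must differ")

    @property
    def L(self) -> int:
        return len(self.seq_a)

    @property
    def labels(self) -> tuple[str, str]:
        return (self.label_a, self.label_b)

    @property
    def polymorphic_sites(self) -> dict[str, list[int]]:
        return {lab: sorted(sites) for lab, sites in self.polymorphism.items()}

    def lineage_seq(self, label: str) -> str:
        if label == self.label_a:
            return self.seq_a
        if label == self.label_b:
            return self.seq_b
        raise KeyError(f"unknown lineage label {label!r}")

    def mito_seq(self, label: str) -> str:
        if label == self.label_a:
            return self.mito_a
        if label == self.label_b:
            return self.mito_b
        raise KeyError(f"unknown lineage label {label!r}")


@dataclass
class DiploidIndividual:
    """A simulated diploid with per-haplotype ancestry truth tracts.

    ``truth_tracts[h]`` tiles ``[0, L)`` with ``(start, end, lineage)``
    intervals for haplotype ``h`` (0 or 1); ``mito_source`` is the maternal
    lineage label.
    """

    sample_id: str
    pedigree_class: str
    hap1: str
    hap2: str
    truth_tracts: tuple[list[tuple[int, int, str]], list[tuple[int, int, str]]]
    mito_source: str
    mito_seq: str = ""

    @property
    def L(self) -> int:
        return len(self.hap1)

    def het_sites(self) -> np.ndarray:
        """Positions where the two haplotypes differ."""
        a = _seq_to_array(self.hap1)
        b = _seq_to_array(self.hap2)
        return np.flatnonzero(a != b)

    def genotype(self, pos: int) -> tuple[str, str]:
        return (self.hap1[pos], self.hap2[pos])

    def tract_lineage(self, hap: int, pos: int) -> str:
        """Ancestry truth at a position on one haplotype."""
        for start, end, lineage in self.truth_tracts[hap]:
            if start <= pos < end:
                return lineage
        raise IndexError(f"position {pos} not covered by truth tracts")


@dataclass
class Pileup:
    """Per-position read evidence: lists of (base, base_quality, mapping_quality).

    ``columns[i]`` holds the reads covering position ``start + i``; the
    depth at a position is simply the length of its column.
    """

    start: int
    columns: list[list[tuple[str, int, int]]]

    @property
    def end(self) -> int:
        return self.start + len(self.columns)

    def __len__(self) -> int:
        return len(self.columns)

    def depths(self) -> np.ndarray:
        return np.array([len(c) for c in self.columns], dtype=int)


@dataclass
class ChecklistTable:
    """Birding-survey records: one row per checklist, with detected species.

    ``records`` columns: checklist_id, locality_id, lon, lat, date,
    complete, species (tuple of names). ``truth`` carries per-detection
    ground-truth labels (resident vs. vagrant, injected co-occurrence) for
    validating the vagrancy filters.
    """

    records: pd.DataFrame
    truth: pd.DataFrame = field(default_factory=pd.DataFrame)

    def __len__(self) -> int:
        return len(self.records)

    def localities(self) -> pd.DataFrame:
        return (
            self.records[["locality_id", "lon", "lat"]]
            .drop_duplicates("locality_id")
            .reset_index(drop=True)
        )


# ---------------------------------------------------------------------------
# Species pair
# ---------------------------------------------------------------------------


def simulate_species_pair(
    L: int,
    divergence: float,
    polymorphism: float = 0.0,
    seed: int | np.random.Generator | None = None,
    label_a: str = "lineage_A",
    label_b: str = "lineage_B",
    mito_length: int = 1000,
    mito_divergence: float | None = None,
) -> ParentalPanel:
    """Simulate two diverged lineages with a known fixed-difference truth table.

    Each autosomal site is independently a fixed difference with probability
    ``divergence``; otherwise it is, with probability ``polymorphism``,
    segregating within exactly one lineage (alternate allele at a minor-allele
    frequency drawn uniformly on [0.05, 0.5]).  The mitochondrial replicon
    diverges at ``mito_divergence`` (defaults to ``divergence``) and carries
    no polymorphism.
    """
    if L < 1:
        raise ValueError("L must be >= 1")
    if not (0.0 <= divergence <= 1.0 and 0.0 <= polymorphism <= 1.0):
        raise ValueError("divergence and polymorphism must be probabilities")
    if divergence + polymorphism > 1.0:
        raise ValueError("divergence + polymorphism must not exceed 1")
    rng = np.random.default_rng(seed)

    seq_a = rng.choice(BASES, size=L)
    seq_b = seq_a.copy()

    u = rng.random(L)
    fixed = np.flatnonzero(u < divergence)
    poly = np.flatnonzero((u >= divergence) & (u < divergence + polymorphism))

    # fixed differences: lineage B gets one of the three non-A bases
    for pos in fixed:
        alts = BASES[BASES != seq_a[pos]]
        seq_b[pos] = rng.choice(alts)

    poly_map: dict[str, dict[int, tuple[str, float]]] = {label_a: {}, label_b: {}}
    for pos in poly:
        lab = label_a if rng.random() < 0.5 else label_b
        ref = seq_a[pos]
        alts = BASES[BASES != ref]
        alt = rng.choice(alts)
        maf = float(rng.uniform(0.05, 0.5))
        poly_map[lab][int(pos)] = (chr(alt), maf)

    if mito_divergence is None:
        mito_divergence = divergence
    mito_a = rng.choice(BASES, size=mito_length)
    mito_b = mito_a.copy()
    mfixed = np.flatnonzero(rng.random(mito_length) < mito_divergence)
    for pos in mfixed:
        alts = BASES[BASES != mito_a[pos]]
        mito_b[pos] = rng.choice(alts)

    return ParentalPanel(
        label_a=label_a,
        label_b=label_b,
        seq_a=_array_to_seq(seq_a),
        seq_b=_array_to_seq(seq_b),
        fixed_sites=fixed.astype(int),
        polymorphism=poly_map,
        mito_a=_array_to_seq(mito_a),
        mito_b=_array_to_seq(mito_b),
    )


# ---------------------------------------------------------------------------
# Crosses
# ---------------------------------------------------------------------------


def _pure_gamete(
    panel: ParentalPanel, label: str, rng: np.random.Generator
) -> tuple[np.ndarray, list[tuple[int, int, str]]]:
    """Draw one haploid gamete from a pure lineage, sampling its polymorphism."""
    seq = _seq_to_array(panel.lineage_seq(label))
    for pos, (alt, maf) in panel.polymorphism.get(label, {}).items():
        if rng.random() < maf:
            seq[pos] = ord(alt)
    return seq, [(0, panel.L, label)]


def _recombine(
    gam1: tuple[np.ndarray, list[tuple[int, int, str]]],
    gam2: tuple[np.ndarray, list[tuple[int, int, str]]],
    recomb_rate: float,
    rng: np.random.Generator,
) -> tuple[np.ndarray, list[tuple[int, int, str]]]:
    """Recombine two parental gametes with Poisson(recomb_rate) crossovers.

    Crossover positions are uniform on the sequence; the transmitted gamete
    starts on a random parental strand and switches at each crossover.
    """
    seq1, tr1 = gam1
    seq2, tr2 = gam2
    L = len(seq1)
    n_cross = rng.poisson(recomb_rate)
    breaks = np.sort(rng.integers(1, L, size=n_cross)) if n_cross else np.array([], int)
    bounds = np.concatenate(([0], breaks, [L])).astype(int)
    cur = int(rng.integers(0, 2))
    out = np.empty(L, dtype=np.uint8)
    tracts: list[tuple[int, int, str]] = []
    for i in range(len(bounds) - 1):
        s, e = int(bounds[i]), int(bounds[i + 1])
        if s == e:
            continue
        src_seq, src_tr = (seq1, tr1) if cur == 0 else (seq2, tr2)
        out[s:e] = src_seq[s:e]
        for ts, te, lab in src_tr:
            os, oe = max(ts, s), min(te, e)
            if os < oe:
                if tracts and tracts[-1][2] == lab and tracts[-1][1] == os:
                    tracts[-1] = (tracts[-1][0], oe, lab)
                else:
                    tracts.append((os, oe, lab))
        cur ^= 1
    return out, tracts


def simulate_cross(
    panel: ParentalPanel,
    pedigree_class: str,
    recomb_rate: float = 1.0,
    seed: int | np.random.Generator | None = None,
    sample_id: str | None = None,
    maternal: str | None = None,
) -> DiploidIndividual:
    """Simulate one diploid of a given pedigree class with ancestry truth tracts.

    F1 pairs one intact gamete from each lineage; F2 and backcross gametes
    are built by Poisson-crossover recombination of an F1's two parental
    haplotypes.  ``maternal`` designates the maternal lineage (defaults to
    ``label_a`` for classes that could have either mother); the
    mitochondrion is inherited from it without heteroplasmy.
    """
    if pedigree_class not in PEDIGREE_CLASSES:
        raise ValueError(
            f"unknown pedigree class {pedigree_class!r}; expected one of {PEDIGREE_CLASSES}"
        )
    rng = np.random.default_rng(seed)
    A, B = panel.label_a, panel.label_b

    def f1_gamete() -> tuple[np.ndarray, list[tuple[int, int, str]]]:
        return _recombine(_pure_gamete(panel, A, rng), _pure_gamete(panel, B, rng), recomb_rate, rng)

    if pedigree_class == "P1":
        g1, g2 = _pure_gamete(panel, A, rng), _pure_gamete(panel, A, rng)
        mito = maternal or A
    elif pedigree_class == "P2":
        g1, g2 = _pure_gamete(panel, B, rng), _pure_gamete(panel, B, rng)
        mito = maternal or B
    elif pedigree_class == "F1":
        g1, g2 = _pure_gamete(panel, A, rng), _pure_gamete(panel, B, rng)
        mito = maternal or A
    elif pedigree_class == "F2":
        g1, g2 = f1_gamete(), f1_gamete()
        mito = maternal or A
    elif pedigree_class == "BC1P1":
        g1, g2 = f1_gamete(), _pure_gamete(panel, A, rng)
        mito = maternal or A
    else:  # BC1P2
        g1, g2 = f1_gamete(), _pure_gamete(panel, B, rng)
        mito = maternal or B

    if mito not in (A, B):
        raise ValueError(f"maternal lineage {mito!r} not in panel")
    if sample_id is None:
        sample_id = f"{pedigree_class}_sim"
    return DiploidIndividual(
        sample_id=sample_id,
        pedigree_class=pedigree_class,
        hap1=_array_to_seq(g1[0]),
        hap2=_array_to_seq(g2[0]),
        truth_tracts=(g1[1], g2[1]),
        mito_source=mito,
        mito_seq=panel.mito_seq(mito),
    )


def genotypes_at(
    ind: DiploidIndividual, positions: Sequence[int]
) -> dict[int, tuple[str, str]]:
    """Extract this individual's diploid genotypes at the given positions."""
    return {int(p): (ind.hap1[p], ind.hap2[p]) for p in positions}


# ---------------------------------------------------------------------------
# Pileups
# ---------------------------------------------------------------------------


def _truncated_normal_int(
    rng: np.random.Generator, mean: float, sd: float, size: int, lo: int = 0, hi: int = 60
) -> np.ndarray:
    vals = np.rint(rng.normal(mean, sd, size=size)).astype(int)
    return np.clip(vals, lo, hi)


def simulate_pileup(
    ind: DiploidIndividual,
    region: tuple[int, int] | None = None,
    mean_depth: float = 8.0,
    error_rate: float = 0.0,
    bq_params: tuple[float, float] = (35.0, 8.0),
    mq_params: tuple[float, float] = (50.0, 12.0),
    seed: int | np.random.Generator | None = None,
) -> Pileup:
    """Simulate per-position read evidence over a region of an individual.

    Depth is Poisson(``mean_depth``); each read samples one haplotype
    uniformly, substitutes a uniformly chosen wrong base with probability
    ``error_rate``, and draws base/mapping qualities from truncated normals
    (mean, sd) clipped to [0, 60].
    """
    if region is None:
        region = (0, ind.L)
    start, end = region
    if end <= start:
        raise ValueError("empty region")
    if mean_depth <= 0:
        raise ValueError("mean_depth must be positive")
    if not (0.0 <= error_rate < 1.0):
        raise ValueError("error_rate must be in [0, 1)")
    rng = np.random.default_rng(seed)

    h1 = _seq_to_array(ind.hap1)[start:end]
    h2 = _seq_to_array(ind.hap2)[start:end]
    n = end - start
    depths = rng.poisson(mean_depth, size=n)
    columns: list[list[tuple[str, int, int]]] = []
    for i in range(n):
        d = int(depths[i])
        if d == 0:
            columns.append([])
            continue
        hap_choice = rng.integers(0, 2, size=d)
        bases = np.where(hap_choice == 0, h1[i], h2[i]).astype(np.uint8)
        if error_rate > 0:
            err = rng.random(d) < error_rate
            for j in np.flatnonzero(err):
                alts = BASES[BASES != bases[j]]
                bases[j] = rng.choice(alts)
        bqs = _truncated_normal_int(rng, *bq_params, size=d)
        mqs = _truncated_normal_int(rng, *mq_params, size=d)
        columns.append(
            [(chr(bases[j]), int(bqs[j]), int(mqs[j])) for j in range(d)]
        )
    return Pileup(start=start, columns=columns)


# ---------------------------------------------------------------------------
# Phase blocks
# ---------------------------------------------------------------------------


def simulate_phase_blocks(
    ind: DiploidIndividual,
    block_length_dist: tuple[float, float] = (340.0, 120.0),
    min_block_gap: int = 10,
    switch_error_rate: float = 0.0,
    seed: int | np.random.Generator | None = None,
    region: tuple[int, int] | None = None,
    scaffold: str = "scaffold_1",
) -> list:
    """Tile an individual's genome with phased haplotype blocks.

    ``block_length_dist`` is the (mean, sd) of a truncated normal over the
    realized block length, i.e. the span from first to last phased variant.
    Because the first/last heterozygous sites sit on average ``1/density``
    inside a sampling window, the generator widens each window by twice the
    individual's mean inter-het distance so that realized spans match the
    requested distribution.

    Within a block the haplotype assignment is consistent except at switch
    errors: at each variant after the first, with probability
    ``switch_error_rate`` the assignment flips for the remainder of the
    block.  Blocks containing no heterozygous site are not emitted.
    """
    from .blocks import PhaseBlock

    mean_len, sd_len = block_length_dist
    if mean_len <= 0:
        raise ValueError("block length distribution must have positive mean")
    if not (0.0 <= switch_error_rate <= 0.5):
        raise ValueError("switch_error_rate must be in [0, 0.5]")
    rng = np.random.default_rng(seed)
    if region is None:
        region = (0, ind.L)
    start, end = region

    het = ind.het_sites()
    het = het[(het >= start) & (het < end)]
    if het.size == 0:
        return []
    density = het.size / (end - start)
    pad = 2.0 / density  # window widening so realized span matches the request

    h1 = _seq_to_array(ind.hap1)
    h2 = _seq_to_array(ind.hap2)
    blocks: list[PhaseBlock] = []
    pos = start
    while pos < end:
        target = rng.normal(mean_len, sd_len)
        window = max(int(round(target + pad)), 2)
        wend = min(pos + window, end)
        vp = het[(het >= pos) & (het < wend)]
        if vp.size >= 1:
            bstart, bend = int(vp[0]), int(vp[-1]) + 1
            b1 = h1[bstart:bend].copy()
            b2 = h2[bstart:bend].copy()
            if switch_error_rate > 0:
                # each toggle flips the assignment from that variant onward
                toggles = [v for v in vp[1:] if rng.random() < switch_error_rate]
                for v in toggles:
                    lo = int(v) - bstart
                    b1[lo:], b2[lo:] = b2[lo:].copy(), b1[lo:].copy()
            blocks.append(
                PhaseBlock(
                    scaffold=scaffold,
                    start=bstart,
                    end=bend,
                    variant_positions=[int(v) for v in vp],
                    hap1_seq=_array_to_seq(b1),
                    hap2_seq=_array_to_seq(b2),
                )
            )
        pos = wend + min_block_gap
    return blocks


# ---------------------------------------------------------------------------
# Checklists
# ---------------------------------------------------------------------------


def simulate_checklists(
    n_localities: int,
    n_years: int,
    detection_rate: float | Mapping[str, float] = 0.3,
    cooccurrence_rate: float = 0.0,
    vagrancy_rate: float = 0.0,
    seed: int | np.random.Generator | None = None,
    species: tuple[str, str] = ("species_a", "species_b"),
    checklists_per_locality_year: float = 4.0,
    start_year: int = 2019,
    extent: tuple[float, float, float, float] = _EARTH_EXTENT,
    range_split: bool = True,
) -> ChecklistTable:
    """Simulate a citizen-science checklist table with ground-truth labels.

    Each locality gets Poisson-distributed checklists per year.  With
    ``range_split`` the two focal species occupy the south and north halves
    of the extent (detections only within range, mimicking mostly allopatric
    ranges); ``cooccurrence_rate`` injects checklists recording both species
    at localities in the middle contact strip, and ``vagrancy_rate`` is the
    per-locality probability of a single out-of-range record in one year
    only.  Truth labels for every detection (resident / vagrant / injected
    co-occurrence) are retained for filter-validation tests.
    """
    if n_localities < 1:
        raise ValueError("n_localities must be >= 1")
    for r in (cooccurrence_rate, vagrancy_rate):
        if not 0.0 <= r <= 1.0:
            raise ValueError("rates must be in [0, 1]")
    rng = np.random.default_rng(seed)
    sp_a, sp_b = species
    if isinstance(detection_rate, Mapping):
        rate = {sp: float(detection_rate.get(sp, 0.0)) for sp in species}
    else:
        rate = {sp: float(detection_rate) for sp in species}

    lon_min, lon_max, lat_min, lat_max = extent
    lons = rng.uniform(lon_min, lon_max, size=n_localities)
    lats = rng.uniform(lat_min, lat_max, size=n_localities)
    lat_mid = 0.5 * (lat_min + lat_max)
    strip = 0.1 * (lat_max - lat_min)

    rows = []
    truth_rows = []
    cid = 0
    years = range(start_year, start_year + n_years)
    for li in range(n_localities):
        loc_id = f"L{li:04d}"
        in_south = lats[li] < lat_mid
        in_contact = abs(lats[li] - lat_mid) < strip
        # species_a southern, species_b northern when range_split
        # strictly allopatric baseline: co-occurrences arise only from
        # injections in the contact strip (or without range_split, by chance)
        local_rate = dict(rate)
        if range_split:
            local_rate[sp_a] = rate[sp_a] if in_south else 0.0
            local_rate[sp_b] = rate[sp_b] if not in_south else 0.0
        vagrant_plan: dict[str, tuple[int, int] | None] = {sp: None for sp in species}
        for sp in species:
            if local_rate[sp] == 0.0 and rng.random() < vagrancy_rate:
                vagrant_plan[sp] = (int(rng.choice(list(years))), -1)

        for year in years:
            n_cl = rng.poisson(checklists_per_locality_year)
            for k in range(n_cl):
                cid += 1
                checklist_id = f"C{cid:06d}"
                day = int(rng.integers(0, 365))
                date = pd.Timestamp(year=year, month=1, day=1) + pd.Timedelta(days=day)
                detected: list[str] = []
                for sp in species:
                    if rng.random() < local_rate[sp]:
                        detected.append(sp)
                        truth_rows.append((checklist_id, loc_id, sp, "resident"))
                if in_contact and rng.random() < cooccurrence_rate:
                    for sp in species:
                        if sp not in detected:
                            detected.append(sp)
                            truth_rows.append((checklist_id, loc_id, sp, "injected_cooccurrence"))
                for sp in species:
                    plan = vagrant_plan[sp]
                    if plan is not None and plan[0] == year and plan[1] == -1 and sp not in detected:
                        detected.append(sp)
                        truth_rows.append((checklist_id, loc_id, sp, "vagrant"))
                        vagrant_plan[sp] = (year, cid)  # only once
                rows.append(
                    (
                        checklist_id,
                        loc_id,
                        float(lons[li]),
                        float(lats[li]),
                        date,
                        True,
                        tuple(sorted(detected)),
                    )
                )
    records = pd.DataFrame(
        rows,
        columns=["checklist_id", "locality_id", "lon", "lat", "date", "complete", "species"],
    )
    truth = pd.DataFrame(truth_rows, columns=["checklist_id", "locality_id", "species", "label"])
    return ChecklistTable(records=records, truth=truth)
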