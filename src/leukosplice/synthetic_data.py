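"""Synthetic input generators with planted ground truth.

Every input the pipeline consumes can be generated here: adapter-flanked
small-RNA reads sampled from a synthetic mature-miRNA reference with
negative-binomial counts and planted fold changes across the four study
conditions (healthy controls, Parkinson's patients pre-treatment, and
post-surgery on/off deep-brain stimulation), log2 junction/exon probe-set
matrices with planted reciprocal splice events, miRNA target-prediction
tables, lineage marker compendia, and independent two-label expression
matrices for classifier checks.

All generators are pure functions of (parameters, seed): repeated calls
with the same arguments are byte-identical.  Each generator emits its
planted truth alongside the data so downstream callers can be scored for
recall and precision.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

__all__ = [
    "CONDITIONS",
    "CONTRASTS",
    "DEFAULT_ADAPTER_5P",
    "DEFAULT_ADAPTER_3P",
    "MiRNARecord",
    "MiRNAReference",
    "StudyDesign",
    "SpliceTruthEvent",
    "PlantedSpliceTruth",
    "SimulatedReadSet",
    "generate_mirna_reference",
    "simulate_reads",
    "simulate_probe_matrix",
    "plant_splice_truth",
    "simulate_target_table",
    "simulate_lineage_compendium",
    "simulate_mixture_samples",
    "simulate_twogroup_matrix",
    "simulate_gene_sets",
]

#: The four leukocyte sampling states, in study order.
CONDITIONS = ("HC", "PD", "DBS_ON", "DBS_OFF")

#: The three tested contrasts (baseline, comparison).
CONTRASTS = (("HC", "PD"), ("PD", "DBS_ON"), ("DBS_ON", "DBS_OFF"))

# SOLiD-style adapter stand-ins.  The 5' adapter is always embedded whole
# (8 nt); the 3' adapter must be long enough to pad any insert out to the
# 35-base core (>= 35 - 8 - 16 = 11 nt).  Border-free by construction —
# the 3' adapter's first base (C) and the 5' adapter's last base (G) occur
# nowhere else in their sequence — so no adapter prefix/suffix overlaps a
# shifted copy of itself and anchored trimming is unambiguous.
DEFAULT_ADAPTER_5P = "CCACTACG"
DEFAULT_ADAPTER_3P = "CAGTGATTGGTAGGATAGTG"

_RNA = np.array(list("ACGU"))
_DNA = np.array(list("ACGT"))


@dataclass(frozen=True)
class MiRNARecord:
    precursor_id: str
    mature_id: str
    mature_sequence: str  # RNA, 18-25 nt
    star_flag: bool = False


@dataclass
class MiRNAReference:
    """Mature/passenger miRNA records grouped by precursor.

    Two precursors may share one mature sequence (and mature_id), mirroring
    miRBase families such as mir-16-1/mir-16-2 -> miR-16.
    """

    records: list[MiRNARecord]

    def __post_init__(self) -> None:
        seen = set()
        for rec in self.records:
            key = (rec.precursor_id, rec.mature_id)
            if key in seen:
                raise ValueError(f"duplicate record {key}")
            seen.add(key)
            if set(rec.mature_sequence) - set("ACGU"):
                raise ValueError(f"non-RNA characters in {rec.mature_id}")

    def __len__(self) -> int:
        return len(self.records)

    def mature_sequences(self) -> dict[str, str]:
        """Unique mature_id -> RNA sequence map (shared groups collapse)."""
        out: dict[str, str] = {}
        for rec in self.records:
            prev = out.setdefault(rec.mature_id, rec.mature_sequence)
            if prev != rec.mature_sequence:
                raise ValueError(
                    f"inconsistent sequences for mature {rec.mature_id}"
                )
        return out

    def to_fasta(self, path) -> None:
        from Bio.Seq import Seq
        from Bio.SeqIO import write as seqio_write
        from Bio.SeqRecord import SeqRecord

        recs = [
            SeqRecord(
                Seq(r.mature_sequence),
                id=f"{r.precursor_id}|{r.mature_id}",
                description="star" if r.star_flag else "mature",
            )
            for r in self.records
        ]
        seqio_write(recs, str(path), "fasta")

    def map_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            [
                (r.precursor_id, r.mature_id, r.mature_sequence, r.star_flag)
                for r in self.records
            ],
            columns=["precursor_id", "mature_id", "mature_sequence", "star_flag"],
        )

    def write_map(self, path) -> None:
        self.map_frame().to_csv(path, sep="\t", index=False)

    @classmethod
    def read_map(cls, path) -> "MiRNAReference":
        df = pd.read_csv(path, sep="\t")
        return cls(
            [
                MiRNARecord(
                    str(r.precursor_id),
                    str(r.mature_id),
                    str(r.mature_sequence),
                    bool(r.star_flag),
                )
                for r in df.itertuples()
            ]
        )


@dataclass
class StudyDesign:
    """Four-condition design with planted differential expression.

    planted_de maps mature_id -> (contrast, log2 fold change); the fold
    change is applied to the contrast's second (comparison) condition.
    """

    libraries_per_condition: int = 3
    planted_de: dict[str, tuple[tuple[str, str], float]] = field(default_factory=dict)
    seed: int = 0
    conditions: tuple[str, ...] = CONDITIONS

    def __post_init__(self) -> None:
        if self.libraries_per_condition < 1:
            raise ValueError("libraries_per_condition must be positive")
        valid = {tuple(c) for c in CONTRASTS}
        for mature, (contrast, _lfc) in self.planted_de.items():
            if tuple(contrast) not in valid:
                raise ValueError(
                    f"planted contrast {contrast!r} for {mature} is not one of {CONTRASTS}"
                )

    @property
    def libraries(self) -> list[tuple[str, str]]:
        """Ordered (library_id, condition) pairs."""
        return [
            (f"{cond}_{i + 1}", cond)
            for cond in self.conditions
            for i in range(self.libraries_per_condition)
        ]

    def groups(self) -> pd.Series:
        libs = self.libraries
        return pd.Series([c for _, c in libs], index=[l for l, _ in libs], name="condition")


@dataclass(frozen=True)
class SpliceTruthEvent:
    gene: str
    inclusion_probe_set: str
    exclusion_probe_set: str | None
    contrast: tuple[str, str]
    direction: str  # "inclusion" | "exclusion"
    effect: float  # log2 units, >= 1 for planted-positive events


@dataclass
class PlantedSpliceTruth:
    events: list[SpliceTruthEvent] = field(default_factory=list)

    def frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            [
                (
                    e.gene,
                    e.inclusion_probe_set,
                    e.exclusion_probe_set or "",
                    f"{e.contrast[0]}-vs-{e.contrast[1]}",
                    e.direction,
                    e.effect,
                )
                for e in self.events
            ],
            columns=[
                "gene",
                "inclusion_probe_set",
                "exclusion_probe_set",
                "contrast",
                "direction",
                "effect",
            ],
        )


def _random_seq(rng: np.random.Generator, length: int, alphabet: np.ndarray) -> str:
    return "".join(rng.choice(alphabet, size=length))


def generate_mirna_reference(
    n_mirnas: int,
    n_star: int = 0,
    seed: int = 0,
    n_shared: int = 1,
    length_range: tuple[int, int] = (18, 25),
) -> MiRNAReference:
    """Generate a synthetic mature/passenger miRNA reference.

    Produces ``n_mirnas`` guide (mature) sequences plus ``n_star`` passenger
    strands attached to the first ``n_star`` precursors.  ``n_shared`` guide
    sequences are each assigned to two precursors (miR-16-style families),
    so the returned record list has ``n_mirnas + n_star + n_shared`` rows
    but ``n_mirnas + n_star`` distinct mature sequences.
    """
    if n_mirnas < 10:
        raise ValueError("n_mirnas must be >= 10")
    if n_star > n_mirnas:
        raise ValueError("n_star cannot exceed n_mirnas")
    if n_shared > n_mirnas:
        raise ValueError("n_shared cannot exceed n_mirnas")
    rng = np.random.default_rng(seed)
    lo, hi = length_range

    sequences: set[str] = set()

    def fresh_seq() -> str:
        while True:
            s = _random_seq(rng, int(rng.integers(lo, hi + 1)), _RNA)
            if s not in sequences:
                sequences.add(s)
                return s

    records: list[MiRNARecord] = []
    shared = set(range(n_shared))
    for i in range(n_mirnas):
        mature_id = f"syn-miR-{i + 1}"
        seq = fresh_seq()
        if i in shared:
            for k in (1, 2):
                records.append(MiRNARecord(f"syn-mir-{i + 1}-{k}", mature_id, seq))
        else:
            records.append(MiRNARecord(f"syn-mir-{i + 1}", mature_id, seq))
        if i < n_star:
            star_id = f"syn-miR-{i + 1}-3p"
            prec = f"syn-mir-{i + 1}-1" if i in shared else f"syn-mir-{i + 1}"
            records.append(MiRNARecord(prec, star_id, fresh_seq(), star_flag=True))
    return MiRNAReference(records)


@dataclass
class SimulatedReadSet:
    """Per-library reads plus the generating truth."""

    reads: dict[str, list[tuple[str, str]]]  # library -> [(read_id, 50-base seq)]
    truth_counts: pd.DataFrame  # mature_id x library, integer reads emitted
    design: StudyDesign
    reference: MiRNAReference

    def write_fastq(self, directory) -> dict[str, str]:
        """One Sanger-quality FASTQ per library (constant Q30)."""
        import pathlib

        directory = pathlib.Path(directory)
        directory.mkdir(parents=True, exist_ok=True)
        paths = {}
        for lib, recs in self.reads.items():
            p = directory / f"{lib}.fastq"
            with open(p, "w") as fh:
                for rid, seq in recs:
                    fh.write(f"@{rid}\n{seq}\n+\n{'?' * len(seq)}\n")
            paths[lib] = str(p)
        return paths


def _build_read(
    rng: np.random.Generator,
    insert: str,
    adapter_5p: str,
    adapter_3p: str,
    read_length: int,
    end_tag_length: int,
) -> str:
    core_len = read_length - end_tag_length
    l5 = len(adapter_5p)
    l3 = core_len - l5 - len(insert)
    if 0 < l3 < 3:
        # A 1-2 base 3' fragment is below any detectable overlap; shift the
        # boundary so the 3' fragment is 3 bases and the 5' fragment shrinks
        # to a 6-7 base adapter suffix (still above the overlap threshold).
        l5 -= 3 - l3
        l3 = 3
    if l3 < 0:
        # Insert longer than the core window: the read runs out (3' clip).
        core = (adapter_5p + insert)[:core_len]
    else:
        if l3 > len(adapter_3p):
            raise ValueError(
                "adapter_3p too short to pad insert of length "
                f"{len(insert)} to the {core_len}-base core"
            )
        core = adapter_5p[len(adapter_5p) - l5 :] + insert + adapter_3p[:l3]
    tag = _random_seq(rng, end_tag_length, _DNA)
    return core + tag


def simulate_reads(
    ref: MiRNAReference,
    design: StudyDesign,
    mean_depth: float = 10_000,
    adapter_5p: str = DEFAULT_ADAPTER_5P,
    adapter_3p: str = DEFAULT_ADAPTER_3P,
    p_iso: float = 0.15,
    p_mm: float = 0.05,
    phi: float = 0.1,
    read_length: int = 50,
    end_tag_length: int = 15,
    seed: int | None = None,
) -> SimulatedReadSet:
    """Simulate adapter-flanked 50-base reads with NB counts per library.

    Each read is (full 5' adapter) + (mature-derived insert) + (3' adapter
    fragment padding to 35 bases) + (15-base random tag end).  With
    probability ``p_iso`` the insert gains or loses up to 2 terminal bases
    (gains are untemplated); with probability ``p_mm`` it carries 1-3
    substitutions.  Per-miRNA expected counts follow a negative binomial
    with dispersion ``phi`` and planted fold changes from the design.
    """
    if not ref.records:
        raise ValueError("empty miRNA reference")
    if phi < 0:
        raise ValueError("phi must be >= 0")
    rng = np.random.default_rng(design.seed if seed is None else seed)

    matures = ref.mature_sequences()
    mature_ids = sorted(matures)
    # Relative abundances: log-normal, heavier weight on a few species.
    weights = rng.lognormal(mean=0.0, sigma=1.0, size=len(mature_ids))
    weights /= weights.sum()

    libs = design.libraries
    counts = np.zeros((len(mature_ids), len(libs)), dtype=int)
    reads: dict[str, list[tuple[str, str]]] = {}
    for j, (lib, cond) in enumerate(libs):
        lib_reads: list[tuple[str, str]] = []
        for g, mid in enumerate(mature_ids):
            mu = mean_depth * weights[g]
            planted = design.planted_de.get(mid)
            if planted is not None:
                (c1, c2), lfc = planted
                if cond == c2:
                    mu *= 2.0 ** lfc
            if phi > 0:
                n_reads = rng.negative_binomial(1.0 / phi, 1.0 / (1.0 + phi * mu))
            else:
                n_reads = rng.poisson(mu)
            counts[g, j] = n_reads
            dna = matures[mid].replace("U", "T")
            for k in range(n_reads):
                insert = dna
                if p_iso > 0 and rng.random() < p_iso:
                    end = rng.integers(2)  # 0: 5', 1: 3'
                    delta = int(rng.choice([-2, -1, 1, 2]))
                    if delta < 0 and len(insert) + delta >= 16:
                        insert = insert[-delta:] if end == 0 else insert[:delta]
                    elif delta > 0:
                        ext = _random_seq(rng, delta, _DNA)
                        insert = ext + insert if end == 0 else insert + ext
                if p_mm > 0 and rng.random() < p_mm:
                    n_sub = int(rng.integers(1, 4))
                    pos = rng.choice(len(insert), size=min(n_sub, len(insert)), replace=False)
                    chars = list(insert)
                    for p in pos:
                        chars[p] = rng.choice([b for b in "ACGT" if b != chars[p]])
                    insert = "".join(chars)
                seq = _build_read(rng, insert, adapter_5p, adapter_3p, read_length, end_tag_length)
                lib_reads.append((f"{lib}:{mid}:{k}", seq))
        reads[lib] = lib_reads

    truth = pd.DataFrame(counts, index=mature_ids, columns=[l for l, _ in libs])
    return SimulatedReadSet(reads=reads, truth_counts=truth, design=design, reference=ref)


# ---------------------------------------------------------------------------
# Junction / exon probe-set matrices
# ---------------------------------------------------------------------------

_EVENT_ANNOTATIONS = (
    "cassette-exon",
    "alt-3prime",
    "alt-5prime",
    "intron-retention",
    "alt-promoter",
    "alt-C-terminal",
    "polyA-site",
)


def _gene_name(i: int) -> str:
    return f"G{i + 1:04d}"


def plant_splice_truth(
    n_genes: int,
    n_events: int,
    contrast: tuple[str, str] = ("HC", "PD"),
    effect: float = 1.5,
    direction: str = "inclusion",
    exon_level: bool = False,
    seed: int = 0,
    start_gene: int = 0,
) -> PlantedSpliceTruth:
    """Assign planted splice events to the first ``n_events`` genes.

    Probe-set names follow the canonical layout emitted by
    :func:`simulate_probe_matrix` ("<gene>_incl"/"<gene>_excl"/"<gene>_psr").
    """
    if n_events > n_genes - start_gene:
        raise ValueError("more events than available genes")
    if effect < 1:
        raise ValueError("planted-positive events must have effect >= 1")
    events = []
    for i in range(start_gene, start_gene + n_events):
        g = _gene_name(i)
        if exon_level:
            events.append(
                SpliceTruthEvent(g, f"{g}_psr", None, tuple(contrast), direction, effect)
            )
        else:
            events.append(
                SpliceTruthEvent(
                    g, f"{g}_incl", f"{g}_excl", tuple(contrast), direction, effect
                )
            )
    return PlantedSpliceTruth(events)


def simulate_probe_matrix(
    n_genes: int,
    design: StudyDesign,
    truth: PlantedSpliceTruth | None = None,
    noise_sd: float = 0.2,
    samples_per_condition: int = 6,
    conditions: tuple[str, ...] = ("HC", "PD", "DBS_ON"),
    codirectional_decoys: PlantedSpliceTruth | None = None,
    seed: int | None = None,
    probe_seq_length: int = 40,
):
    """Simulate a log2 junction/exon probe-set matrix with planted events.

    Per gene: two constitutive probe sets, one reciprocal
    inclusion/exclusion junction pair, and one exon/PSR probe set.  Planted
    events add ``+effect`` to the inclusion probe set and ``-effect`` to the
    exclusion probe set (or vice versa for direction "exclusion") in the
    contrast's second condition.  Exon-level events shift the PSR probe only.
    Co-directional decoys shift both members of the pair the same way and
    must never be called by the reciprocal-junction detector.

    Returns ``(ProbeSetMatrix, PlantedSpliceTruth)``.
    """
    from .splicing import ProbeSetMatrix

    if noise_sd < 0:
        raise ValueError("noise_sd must be >= 0")
    truth = truth if truth is not None else PlantedSpliceTruth([])
    rng = np.random.default_rng(design.seed if seed is None else seed)

    samples = [
        f"{cond}_s{i + 1}" for cond in conditions for i in range(samples_per_condition)
    ]
    sample_cond = {s: s.rsplit("_s", 1)[0] for s in samples}

    probe_rows = []
    ann_rows = []
    for i in range(n_genes):
        g = _gene_name(i)
        base = rng.uniform(6.0, 10.0)
        layout = [
            (f"{g}_const1", "constitutive", ""),
            (f"{g}_const2", "constitutive", ""),
            (f"{g}_incl", "junction_inclusion", f"{g}_excl"),
            (f"{g}_excl", "junction_exclusion", f"{g}_incl"),
            (f"{g}_psr", "exon_psr", ""),
        ]
        event_ann = _EVENT_ANNOTATIONS[int(rng.integers(len(_EVENT_ANNOTATIONS)))]
        for probe, role, partner in layout:
            offset = rng.uniform(-1.0, 1.0)
            probe_rows.append((probe, base + offset))
            ann_rows.append(
                (
                    probe,
                    g,
                    role,
                    partner,
                    _random_seq(rng, probe_seq_length, _DNA),
                    event_ann if role.startswith("junction") else "",
                )
            )

    probe_index = [p for p, _ in probe_rows]
    means = np.array([m for _, m in probe_rows])
    x = means[:, None] + (
        rng.normal(0.0, noise_sd, size=(len(probe_index), len(samples)))
        if noise_sd > 0
        else 0.0
    )
    x = pd.DataFrame(np.asarray(x, dtype=float) * np.ones((len(probe_index), len(samples))),
                     index=probe_index, columns=samples)

    pos = {p: k for k, p in enumerate(probe_index)}
    cond_cols = {
        c: [j for j, s in enumerate(samples) if sample_cond[s] == c] for c in conditions
    }

    def apply_event(ev: SpliceTruthEvent, reciprocal: bool) -> None:
        _c1, c2 = ev.contrast
        if c2 not in cond_cols:
            raise ValueError(f"contrast condition {c2} not among simulated conditions")
        cols = cond_cols[c2]
        sign = 1.0 if ev.direction == "inclusion" else -1.0
        x.iloc[pos[ev.inclusion_probe_set], cols] += sign * ev.effect
        if ev.exclusion_probe_set:
            x.iloc[pos[ev.exclusion_probe_set], cols] += (
                sign * ev.effect if not reciprocal else -sign * ev.effect
            )

    for ev in truth.events:
        apply_event(ev, reciprocal=True)
    if codirectional_decoys is not None:
        for ev in codirectional_decoys.events:
            apply_event(ev, reciprocal=False)

    annotations = pd.DataFrame(
        ann_rows,
        columns=["probe_set", "gene", "role", "reciprocal_partner", "sequence", "event_annotation"],
    ).set_index("probe_set")

    matrix = ProbeSetMatrix(
        intensities=x, annotations=annotations, sample_conditions=pd.Series(sample_cond)
    )
    return matrix, truth


def simulate_target_table(
    ref: MiRNAReference,
    genes: list[str],
    density: float = 2.0,
    region_probs: tuple[float, float, float] = (0.19, 0.38, 0.43),
    exact_density: bool = True,
    seed: int = 0,
    max_offset: int = 2000,
) -> pd.DataFrame:
    """Simulate a miRNA -> gene site-prediction table.

    ``region_probs`` is the (5UTR, CDS, 3UTR) sampling simplex; the default
    mirrors the observed 19/38/43% split of predicted sites across gene
    regions in disease-network predictions.
    """
    if density <= 0:
        raise ValueError("density must be > 0")
    probs = np.asarray(region_probs, dtype=float)
    if probs.min() < 0 or not np.isclose(probs.sum(), 1.0):
        raise ValueError("region_probs must be a probability simplex")
    rng = np.random.default_rng(seed)
    mirnas = sorted(ref.mature_sequences())
    n_rows = int(round(density * len(genes))) if exact_density else int(
        rng.poisson(density * len(genes))
    )
    regions = ("5UTR", "CDS", "3UTR")
    rows = []
    seen = set()
    while len(rows) < n_rows:
        m = mirnas[int(rng.integers(len(mirnas)))]
        g = genes[int(rng.integers(len(genes)))]
        reg = regions[int(rng.choice(3, p=probs))]
        off = int(rng.integers(max_offset))
        key = (m, g, reg, off)
        if key in seen:
            continue
        seen.add(key)
        rows.append(key)
    return pd.DataFrame(rows, columns=["mirna", "gene", "region", "site_offset"])


def simulate_lineage_compendium(
    n_lineages: int = 8,
    markers_per_lineage: int = 100,
    n_samples: int = 3,
    shift: float = 3.0,
    noise_sd: float = 0.5,
    n_background_genes: int = 200,
    seed: int = 0,
):
    """Block-structured lineage compendium with ``n_samples`` columns/lineage.

    Each lineage elevates its own ``markers_per_lineage`` marker genes by
    ``shift`` log2 units over a common baseline.  Returns ``(compendium,
    labels, truth)`` where truth records the planted marker sets and the
    noiseless lineage profiles.
    """
    if not 50 <= markers_per_lineage <= 150:
        warnings.warn(
            f"markers_per_lineage={markers_per_lineage} outside the typical 50-150 range",
            stacklevel=2,
        )
    rng = np.random.default_rng(seed)
    lineages = [f"lineage_{chr(ord('A') + i)}" for i in range(n_lineages)]
    genes = [f"LG{i + 1:05d}" for i in range(n_lineages * markers_per_lineage + n_background_genes)]
    marker_sets = {
        l: genes[i * markers_per_lineage : (i + 1) * markers_per_lineage]
        for i, l in enumerate(lineages)
    }
    baseline = rng.uniform(4.0, 8.0, size=len(genes))
    profiles = pd.DataFrame(
        np.tile(baseline[:, None], (1, n_lineages)), index=genes, columns=lineages
    )
    for i, l in enumerate(lineages):
        profiles.iloc[i * markers_per_lineage : (i + 1) * markers_per_lineage, i] += shift

    cols, labels = [], []
    data = []
    for l in lineages:
        for k in range(n_samples):
            cols.append(f"{l}_rep{k + 1}")
            labels.append(l)
            noise = rng.normal(0.0, noise_sd, size=len(genes)) if noise_sd > 0 else 0.0
            data.append(profiles[l].to_numpy() + noise)
    compendium = pd.DataFrame(np.column_stack(data), index=genes, columns=cols)
    truth = {"marker_sets": marker_sets, "profiles": profiles}
    return compendium, pd.Series(labels, index=cols, name="lineage"), truth


def simulate_mixture_samples(
    profiles: pd.DataFrame,
    weights: dict[str, float],
    n_samples: int,
    noise_sd: float = 0.5,
    seed: int = 0,
):
    """Mixture expression samples from noiseless lineage profiles.

    Returns ``(samples, dominant)`` where dominant is the highest-weight
    lineage label recorded for every sample.
    """
    w = pd.Series(weights, dtype=float)
    if not np.isclose(w.sum(), 1.0):
        raise ValueError("mixture weights must sum to 1")
    missing = set(w.index) - set(profiles.columns)
    if missing:
        raise ValueError(f"unknown lineages in weights: {sorted(missing)}")
    rng = np.random.default_rng(seed)
    mix = profiles[w.index].to_numpy() @ w.to_numpy()
    cols = [f"mix_s{i + 1}" for i in range(n_samples)]
    noise = rng.normal(0.0, noise_sd, size=(len(profiles), n_samples)) if noise_sd > 0 else 0.0
    samples = pd.DataFrame(mix[:, None] + noise, index=profiles.index, columns=cols)
    dominant = pd.Series(w.idxmax(), index=cols, name="dominant_lineage")
    return samples, dominant


def simulate_twogroup_matrix(
    n_features: int = 300,
    group_sizes: tuple[int, int] = (24, 23),
    effect: float = 2.0,
    noise_sd: float = 1.0,
    seed: int = 0,
):
    """Independent two-label expression matrix for classifier checks.

    Every feature is shifted by ``effect`` (in units of ``noise_sd`` when
    noise_sd=1) in the second group.  Returns ``(matrix, labels)``.
    """
    rng = np.random.default_rng(seed)
    n1, n2 = group_sizes
    cols = [f"ctl_{i + 1}" for i in range(n1)] + [f"case_{i + 1}" for i in range(n2)]
    labels = pd.Series(["ctl"] * n1 + ["case"] * n2, index=cols, name="label")
    base = rng.uniform(5.0, 9.0, size=n_features)
    x = base[:, None] + rng.normal(0.0, noise_sd, size=(n_features, n1 + n2))
    signs = rng.choice([-1.0, 1.0], size=n_features)
    x[:, n1:] += (signs * effect)[:, None]
    idx = [f"F{i + 1:04d}" for i in range(n_features)]
    return pd.DataFrame(x, index=idx, columns=cols), labels


def simulate_gene_sets(
    genes: list[str],
    n_sets: int = 20,
    set_size_range: tuple[int, int] = (10, 40),
    seed: int = 0,
) -> dict[str, list[str]]:
    """Random flat gene sets over ``genes`` (GMT-style)."""
    rng = np.random.default_rng(seed)
    lo, hi = set_size_range
    out = {}
    for i in range(n_sets):
        size = int(rng.integers(lo, min(hi, len(genes)) + 1))
        members = list(rng.choice(genes, size=size, replace=False))
        out[f"SET_{i + 1:03d}"] = sorted(members)
    return out
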