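"""Forward simulators for every input the pipeline consumes.

Three generators, each with full truth serialization:

* read alignments (SAM) from a replicating circular chromosome whose
  coverage decays exponentially from the replication origin to the terminus
  at a rate set by a known peak-to-trough ratio (PTR);
* a log-linear samples x virtual-contigs coverage matrix that bypasses read
  sampling for fast tests;
* a metabolite intensity table with region / bioreplicate / treatment
  structure, plus a compositional community table sharing latent factors
  with the metabolome so that microbiome-metabolome congruence is tunable.

All randomness flows from one seeded generator per invocation; identical
seeds give byte-identical outputs.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import pysam

from .coverage import split_virtual_contigs
from .metabolites import BIOREPLICATES, MetaboliteTable, REGIONS, TREATMENTS

__all__ = [
    "GenomeModel",
    "ReplicationScenario",
    "MetabolomeScenario",
    "SimulationTruth",
    "simulate_alignments",
    "simulate_coverage_matrix",
    "simulate_metabolome",
    "write_truth",
    "read_truth",
]

_NUCLEOTIDES = np.array(list("ACGT"))


@dataclass
class GenomeModel:
    """A single circular chromosome replicating bidirectionally from oriC."""

    length: int
    ori_position: int = 0
    circular: bool = True
    sequence: str | None = None

    def __post_init__(self) -> None:
        if self.length <= 0:
            raise ValueError("genome length must be positive")
        if not 0 <= self.ori_position < self.length:
            raise ValueError("ori_position must lie in [0, length)")
        if self.sequence is not None and len(self.sequence) != self.length:
            raise ValueError("sequence length must equal genome length")

    def folded_distance(self, position) -> np.ndarray:
        """Relative distance from oriC along the shorter replichore, in [0, 1].

        0 at the origin, 1 at the terminus (the point diametrically opposite
        on the circle).
        """
        t = np.asarray(position, dtype=float) - self.ori_position
        t = np.mod(t, self.length)
        return (2.0 / self.length) * np.minimum(t, self.length - t)

    def ensure_sequence(self, rng: np.random.Generator) -> str:
        if self.sequence is None:
            self.sequence = "".join(rng.choice(_NUCLEOTIDES, size=self.length))
        return self.sequence


@dataclass
class ReplicationScenario:
    """Per-sample PTRs and read-sampling settings for :func:`simulate_alignments`."""

    ptr_per_sample: list[float]
    reads_per_sample: int = 50_000
    read_length: int = 100
    noise_sd: float = 0.0  # log2-scale multiplicative coverage noise
    fraction_low_quality: float = 0.0
    seed: int = 0

    def __post_init__(self) -> None:
        if not self.ptr_per_sample:
            raise ValueError("at least one sample PTR required")
        if any(p < 1.0 for p in self.ptr_per_sample):
            raise ValueError("every PTR must be >= 1 (non-positive gradients are rejected)")
        if self.reads_per_sample <= 0:
            raise ValueError("reads_per_sample must be positive")
        if self.read_length <= 0:
            raise ValueError("read_length must be positive")
        if self.noise_sd < 0:
            raise ValueError("noise_sd must be non-negative")
        if not 0.0 <= self.fraction_low_quality <= 1.0:
            raise ValueError("fraction_low_quality must be in [0, 1]")

    @property
    def sample_ids(self) -> list[str]:
        return [f"S{i + 1:02d}" for i in range(len(self.ptr_per_sample))]


@dataclass
class MetabolomeScenario:
    """Study-condition parameters for :func:`simulate_metabolome`.

    Defaults emulate the source study: 654 profiled metabolites of which 24%
    respond to treatment, three colon regions x three bioreplicates x two
    treatment phases, and a small set of AC-restricted metabolites that fall
    below detection outside the ascending colon (the Trp/Tyr pattern).
    """

    n_metabolites: int = 654
    n_samples_per_cell: int = 3
    frac_treatment_affected: float = 0.24
    treatment_effect_log2: float = 1.0
    region_effect_log2: float = 1.0
    frac_region_restricted: float = 0.05
    noise_sd_log2: float = 0.5
    congruence_strength: float = 0.5
    seed: int = 0
    n_taxa: int = 40

    def __post_init__(self) -> None:
        if self.n_metabolites < 1:
            raise ValueError("n_metabolites must be >= 1")
        if self.n_samples_per_cell < 1:
            raise ValueError("n_samples_per_cell must be >= 1")
        for name in ("frac_treatment_affected", "frac_region_restricted", "congruence_strength"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"{name} must be in [0, 1]")
        if self.noise_sd_log2 < 0:
            raise ValueError("noise_sd_log2 must be non-negative")


@dataclass
class SimulationTruth:
    """Ground truth emitted alongside every simulated dataset."""

    true_ptr: dict[str, float] = field(default_factory=dict)
    true_distance: dict[str, float] = field(default_factory=dict)
    affected_metabolites: set[str] = field(default_factory=set)
    region_restricted_metabolites: dict[str, str] = field(default_factory=dict)
    latent_factors: pd.DataFrame | None = None
    low_quality_reads: dict[str, list[str]] = field(default_factory=dict)

    def __eq__(self, other) -> bool:
        if not isinstance(other, SimulationTruth):
            return NotImplemented
        if (self.latent_factors is None) != (other.latent_factors is None):
            return False
        lf_equal = (
            self.latent_factors is None
            or np.allclose(self.latent_factors.values, other.latent_factors.values)
            and list(self.latent_factors.index) == list(other.latent_factors.index)
        )
        return (
            self.true_ptr == other.true_ptr
            and self.true_distance == other.true_distance
            and self.affected_metabolites == other.affected_metabolites
            and self.region_restricted_metabolites == other.region_restricted_metabolites
            and self.low_quality_reads == other.low_quality_reads
            and lf_equal
        )


def write_truth(truth: SimulationTruth, path) -> None:
    """Serialize truth as a flat key/value TSV (round-trips exactly)."""
    with open(path, "w") as fh:
        fh.write("key\tvalue\n")
        for sample, ptr in truth.true_ptr.items():
            fh.write(f"true_ptr.{sample}\t{ptr!r}\n")
        for contig, d in truth.true_distance.items():
            fh.write(f"true_distance.{contig}\t{d!r}\n")
        for m in sorted(truth.affected_metabolites):
            fh.write(f"affected.{m}\t1\n")
        for m, region in truth.region_restricted_metabolites.items():
            fh.write(f"restricted.{m}\t{region}\n")
        if truth.latent_factors is not None:
            for sample, row in truth.latent_factors.iterrows():
                for k, v in enumerate(row.values):
                    fh.write(f"latent.{sample}.{k}\t{float(v)!r}\n")
        for sample, names in truth.low_quality_reads.items():
            for name in names:
                fh.write(f"low_quality.{sample}.{name}\t1\n")


def read_truth(path) -> SimulationTruth:
    truth = SimulationTruth()
    latent: dict[str, dict[int, float]] = {}
    frame = pd.read_csv(path, sep="\t", dtype=str)
    for key, value in zip(frame["key"], frame["value"]):
        kind, _, rest = key.partition(".")
        if kind == "true_ptr":
            truth.true_ptr[rest] = float(value)
        elif kind == "true_distance":
            truth.true_distance[rest] = float(value)
        elif kind == "affected":
            truth.affected_metabolites.add(rest)
        elif kind == "restricted":
            truth.region_restricted_metabolites[rest] = value
        elif kind == "latent":
            sample, _, k = rest.rpartition(".")
            latent.setdefault(sample, {})[int(k)] = float(value)
        elif kind == "low_quality":
            sample, _, name = rest.partition(".")
            truth.low_quality_reads.setdefault(sample, []).append(name)
    if latent:
        truth.latent_factors = pd.DataFrame(
            {s: pd.Series(v) for s, v in latent.items()}
        ).T.sort_index(axis=1)
        truth.latent_factors = truth.latent_factors.loc[sorted(latent)]
    return truth


# ---------------------------------------------------------------------------
# read-level simulation
# ---------------------------------------------------------------------------

def _sample_distances(rng: np.random.Generator, n: int, ptr: float) -> np.ndarray:
    """Draw folded distances d in [0, 1] with density proportional to PTR^-d.

    Closed-form inverse CDF of the truncated exponential; exact, no
    rejection step.
    """
    u = rng.random(n)
    lam = np.log(ptr)
    if lam < 1e-12:
        return u
    return -np.log1p(-u * (1.0 - np.exp(-lam))) / lam


def _sample_start_positions(
    rng: np.random.Generator,
    n: int,
    ptr: float,
    genome: GenomeModel,
    read_length: int,
    noise_sd: float,
    n_noise_bins: int = 100,
) -> np.ndarray:
    """Read start positions from c(x) ~ PTR^-d(x), optionally bin-jittered.

    With ``noise_sd > 0`` each replichore is divided into ``n_noise_bins``
    equal distance bins whose weights are multiplied by 2^N(0, noise_sd^2);
    within the chosen bin the exact truncated-exponential draw applies.
    Starts that would run past the linear end of the reference are redrawn
    (a circular alignment cannot be represented in a single SAM record).
    """
    L = genome.length
    half = L / 2.0
    max_start = L - read_length

    def draw(k: int) -> np.ndarray:
        if noise_sd > 0:
            lam = np.log(ptr)
            edges = np.linspace(0.0, 1.0, n_noise_bins + 1)
            if lam < 1e-12:
                base = np.diff(edges)
            else:
                base = (np.exp(-lam * edges[:-1]) - np.exp(-lam * edges[1:])) / lam
            # independent noise per bin per replichore
            w = np.concatenate(
                [
                    base * np.exp2(rng.normal(0.0, noise_sd, n_noise_bins)),
                    base * np.exp2(rng.normal(0.0, noise_sd, n_noise_bins)),
                ]
            )
            w = w / w.sum()
            choice = rng.choice(2 * n_noise_bins, size=k, p=w)
            side = np.where(choice < n_noise_bins, 1.0, -1.0)
            b = np.where(choice < n_noise_bins, choice, choice - n_noise_bins)
            lo, hi = edges[b], edges[b + 1]
            u = rng.random(k)
            if lam < 1e-12:
                d = lo + u * (hi - lo)
            else:
                elo, ehi = np.exp(-lam * lo), np.exp(-lam * hi)
                d = -np.log(elo - u * (elo - ehi)) / lam
        else:
            d = _sample_distances(rng, k, ptr)
            side = np.where(rng.random(k) < 0.5, 1.0, -1.0)
        pos = np.mod(genome.ori_position + side * d * half, L)
        return np.floor(pos).astype(np.int64)

    starts = draw(n)
    bad = starts > max_start
    while bad.any():
        starts[bad] = draw(int(bad.sum()))
        bad = starts > max_start
    return starts


def simulate_alignments(
    genome: GenomeModel,
    scenario: ReplicationScenario,
    out_dir,
    n_contigs: int = 20,
) -> tuple[list[Path], SimulationTruth]:
    """Write one SAM file per sample plus the simulation truth.

    Read start positions follow the replication coverage gradient
    ``c(x) ~ PTR^-d(x)`` so that the expected origin/terminus coverage ratio
    equals the sample's PTR.  A ``fraction_low_quality`` of records is
    emitted so as to fail exactly one of the three alignment filters (short
    alignment, MAPQ 2, or mismatch ratio 0.05 via the NM tag); their read
    names are recorded in the truth.  Also writes the reference FASTA.
    """
    if scenario.read_length >= genome.length:
        raise ValueError("read_length must be smaller than the genome")
    if genome.length < 10 * scenario.read_length:
        raise ValueError("genome must be at least 10 read lengths long")
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    # sequence generation uses its own stream so that a genome with or
    # without a pre-set sequence yields the same read draws for one seed
    seq_ss, read_ss = np.random.SeedSequence(scenario.seed).spawn(2)
    seq = genome.ensure_sequence(np.random.default_rng(seq_ss))
    rng = np.random.default_rng(read_ss)
    ref_name = "ref"

    fasta_path = out_dir / "reference.fasta"
    with open(fasta_path, "w") as fh:
        fh.write(f">{ref_name}\n")
        for i in range(0, genome.length, 70):
            fh.write(seq[i : i + 70] + "\n")

    contigs = split_virtual_contigs(genome.length, n_contigs)
    truth = SimulationTruth(
        true_distance={
            c.name: float(genome.folded_distance(c.midpoint)) for c in contigs
        }
    )
    header = {
        "HD": {"VN": "1.6", "SO": "coordinate"},
        "SQ": [{"SN": ref_name, "LN": genome.length}],
    }
    rl = scenario.read_length
    short_len = min(30, rl - 1)
    paths = []
    for sample, ptr in zip(scenario.sample_ids, scenario.ptr_per_sample):
        truth.true_ptr[sample] = float(ptr)
        n = scenario.reads_per_sample
        starts = _sample_start_positions(
            rng, n, ptr, genome, rl, scenario.noise_sd
        )
        low = rng.random(n) < scenario.fraction_low_quality
        mode = rng.integers(0, 3, size=n)
        order = np.argsort(starts, kind="stable")
        sam_path = out_dir / f"{sample}.sam"
        lowq_names: list[str] = []
        with pysam.AlignmentFile(str(sam_path), "w", header=header) as fh:
            for rank, idx in enumerate(order):
                start = int(starts[idx])
                a = pysam.AlignedSegment(fh.header)
                a.query_name = f"{sample}_r{idx:07d}"
                a.reference_id = 0
                a.reference_start = start
                a.query_sequence = seq[start : start + rl]
                a.flag = 0
                if low[idx]:
                    lowq_names.append(a.query_name)
                    m = mode[idx]
                    if m == 0:  # too short
                        a.cigarstring = f"{short_len}M{rl - short_len}S"
                        a.mapping_quality = 40
                        a.set_tag("NM", 0)
                    elif m == 1:  # low mapping quality
                        a.cigarstring = f"{rl}M"
                        a.mapping_quality = 2
                        a.set_tag("NM", 0)
                    else:  # mismatch ratio 0.05 > 0.03
                        a.cigarstring = f"{rl}M"
                        a.mapping_quality = 40
                        a.set_tag("NM", int(np.ceil(0.05 * rl)))
                else:
                    a.cigarstring = f"{rl}M"
                    a.mapping_quality = 40
                    a.set_tag("NM", 0)
                fh.write(a)
        truth.low_quality_reads[sample] = lowq_names
        paths.append(sam_path)
    write_truth(truth, out_dir / "truth.tsv")
    return paths, truth


# ---------------------------------------------------------------------------
# matrix-level simulation
# ---------------------------------------------------------------------------

def simulate_coverage_matrix(
    genome: GenomeModel,
    scenario: ReplicationScenario,
    n_contigs: int = 20,
    shuffle: bool = False,
) -> tuple[pd.DataFrame, SimulationTruth]:
    """Log-linear coverage matrix without read sampling.

    ``y[s, c] = a_s - log2(PTR_s) * d_c + Normal(0, noise_sd^2)`` with d_c
    the folded distance of the contig midpoint from oriC.  With ``shuffle``
    the contig column order is permuted (ids travel with their columns; true
    distances are in the truth).
    """
    if n_contigs < 4:
        raise ValueError("n_contigs must be >= 4")
    rng = np.random.default_rng(scenario.seed)
    contigs = split_virtual_contigs(genome.length, n_contigs)
    d = np.array([genome.folded_distance(c.midpoint) for c in contigs])
    samples = scenario.sample_ids
    ptr = np.array(scenario.ptr_per_sample, dtype=float)
    a = rng.normal(5.0, 0.5, size=len(samples))
    y = a[:, None] - np.log2(ptr)[:, None] * d[None, :]
    if scenario.noise_sd > 0:
        y = y + rng.normal(0.0, scenario.noise_sd, size=y.shape)
    frame = pd.DataFrame(y, index=samples, columns=[c.name for c in contigs])
    truth = SimulationTruth(
        true_ptr={s: float(p) for s, p in zip(samples, ptr)},
        true_distance={c.name: float(di) for c, di in zip(contigs, d)},
    )
    if shuffle:
        frame = frame.iloc[:, rng.permutation(n_contigs)]
    return frame, truth


# ---------------------------------------------------------------------------
# metabolome + community simulation
# ---------------------------------------------------------------------------

def _orthonormal_loadings(rng: np.random.Generator, n: int, k: int) -> np.ndarray:
    """n x k matrix with orthonormal columns scaled to unit per-entry RMS."""
    q, _ = np.linalg.qr(rng.normal(size=(n, k)))
    return q * np.sqrt(n)


def simulate_metabolome(
    scenario: MetabolomeScenario,
) -> tuple[MetaboliteTable, pd.DataFrame, SimulationTruth]:
    """Metabolite table, community table and truth with shared latent factors.

    log2 intensity = baseline + region effect + bioreplicate effect
    + treatment effect (affected metabolites, LGG samples only)
    + congruence_strength * (latent factor . loading) + noise.

    AC-restricted metabolites sit near the detection floor outside the
    ascending colon; any linear intensity below the floor (1/100 of the
    median baseline) is reported missing.  The community table is a softmax
    of taxon loadings on the same latent factors plus independent logit
    noise; rows sum to 1.
    """
    rng = np.random.default_rng(scenario.seed)
    k = 2
    cells = [
        (region, br, trt, i)
        for region in REGIONS
        for br in BIOREPLICATES
        for trt in TREATMENTS
        for i in range(scenario.n_samples_per_cell)
    ]
    meta_rows = []
    for region, br, trt, i in cells:
        sid = f"{region}_{br}_{trt}_r{i + 1:02d}"
        meta_rows.append(
            {
                "sample_id": sid,
                "region": region,
                "bioreplicate": br,
                "treatment": trt,
                "day": 3 * (i % 3 + 1),
            }
        )
    metadata = (
        pd.DataFrame(meta_rows).set_index("sample_id").sort_index()
    )
    samples = metadata.index
    n_samples = len(samples)
    m = scenario.n_metabolites
    met_ids = [f"M{i + 1:04d}" for i in range(m)]

    baseline = rng.normal(10.0, 1.0, size=m)
    region_eff = rng.normal(0.0, scenario.region_effect_log2, size=(m, len(REGIONS)))
    br_eff = rng.normal(0.0, 0.5 * scenario.region_effect_log2, size=(m, len(BIOREPLICATES)))

    n_affected = int(round(scenario.frac_treatment_affected * m))
    perm = rng.permutation(m)
    affected_idx = perm[:n_affected]
    n_restricted = int(round(scenario.frac_region_restricted * m))
    restricted_idx = perm[n_affected : n_affected + n_restricted]
    treat_sign = rng.choice([-1.0, 1.0], size=m)
    treat_eff = np.zeros(m)
    treat_eff[affected_idx] = scenario.treatment_effect_log2 * treat_sign[affected_idx]

    latent = rng.normal(size=(n_samples, k))
    met_load = _orthonormal_loadings(rng, m, k) * 0.5
    taxa_load = _orthonormal_loadings(rng, scenario.n_taxa, k)

    region_idx = metadata["region"].map({r: i for i, r in enumerate(REGIONS)}).values
    br_idx = metadata["bioreplicate"].map({b: i for i, b in enumerate(BIOREPLICATES)}).values
    is_lgg = (metadata["treatment"] == "LGG").values.astype(float)

    log2_int = (
        baseline[None, :]
        + region_eff[:, region_idx].T
        + br_eff[:, br_idx].T
        + is_lgg[:, None] * treat_eff[None, :]
        + scenario.congruence_strength * (latent @ met_load.T)
        + rng.normal(0.0, scenario.noise_sd_log2, size=(n_samples, m))
    )

    floor = float(np.median(np.exp2(baseline)) / 100.0)
    floor_log2 = np.log2(floor)
    not_ac = metadata["region"].values != "AC"
    for j in restricted_idx:
        log2_int[not_ac, j] = floor_log2 - 1.0 + rng.normal(
            0.0, 0.5 * scenario.noise_sd_log2, size=int(not_ac.sum())
        )

    linear = np.exp2(log2_int)
    linear[linear < floor] = np.nan
    intensities = pd.DataFrame(linear, index=samples, columns=met_ids)

    annotations = pd.DataFrame(
        {
            "name": [f"metabolite_{i + 1}" for i in range(m)],
            "super_pathway": [f"SUPER{i // 64 + 1:02d}" for i in range(m)],
            "sub_pathway": [f"SP{i // 8 + 1:03d}" for i in range(m)],
            "identified": rng.random(m) < 0.85,
        },
        index=pd.Index(met_ids, name="metabolite"),
    )
    table = MetaboliteTable(
        intensities=intensities, metadata=metadata, annotations=annotations
    )

    logits = latent @ taxa_load.T + rng.normal(
        0.0, 0.5 * scenario.noise_sd_log2, size=(n_samples, scenario.n_taxa)
    )
    expl = np.exp(logits - logits.max(axis=1, keepdims=True))
    community = pd.DataFrame(
        expl / expl.sum(axis=1, keepdims=True),
        index=samples,
        columns=[f"g{i + 1:02d}" for i in range(scenario.n_taxa)],
    )

    truth = SimulationTruth(
        affected_metabolites={met_ids[i] for i in affected_idx},
        region_restricted_metabolites={met_ids[i]: "AC" for i in restricted_idx},
        latent_factors=pd.DataFrame(latent, index=samples, columns=range(k)),
    )
    return table, community, truth
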