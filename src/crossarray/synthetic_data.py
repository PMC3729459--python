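"""Synthetic transcript catalogs, platform probe sets and three-study designs.

The generator emulates the design of a pooled analysis of utero-placental
transcription: three studies on two microarray platforms (two studies on a
multi-probe 25-mer probeset platform, one on a single 50-mer probe platform),
with additive preeclampsia (PE) and per-week gestational-age (GA) effects on
a latent log2-like expression scale, per-study mean shifts, and per-feature
residual variances drawn from a scaled inverse-chi-square prior — so that
every downstream stage (probe mapping, normalization, moderated linear
modelling, pi0 estimation) can be checked against known ground truth.

Generative model, per transcript g and sample i in study s:

    y_gi = mu_g + shift_{g,s} + beta_PE,g * PE_i + beta_GA,g * GA_i + eps_gi
    eps_gi ~ Normal(0, sigma_g^2),  sigma_g^2 ~ s0_sq * d0 / chi2_{d0}

Effects follow a spike-and-slab: a transcript is differentially expressed
(DE) for a covariate with the configured probability, in which case its
effect is Normal(0, sd); otherwise the effect is exactly zero.  The true
non-DE fractions pi0 = 1 - mean(is_DE) are recorded alongside the effects.

All randomness flows from a single integer seed through
``numpy.random.SeedSequence`` child spawning; there is no global state.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

from .exceptions import InvalidArgumentError

logger = logging.getLogger(__name__)

BASES = np.array(list("ACGT"))

AFFY25 = "AFFY25"
ILMN50 = "ILMN50"
PROBE_LENGTH = {AFFY25: 25, ILMN50: 50}

#: Ratio of transcripts to genes used when assigning gene symbols; mirrors a
#: catalog in which 18,180 transcripts collapse to 14,678 genes (~1.24).
TRANSCRIPTS_PER_GENE = 18180 / 14678


# ---------------------------------------------------------------------------
# domain types
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class TranscriptRecord:
    transcript_id: str
    gene_symbol: str
    sequence: str


@dataclass
class TranscriptCatalog:
    """An ordered collection of transcripts with gene annotations.

    ``repeat_sequence`` holds the shared repeat motif planted into some
    transcripts when ``n_repeat_copies > 0`` (an Alu-like element used to
    exercise the promiscuous-probe filter); ``None`` otherwise.
    """

    entries: list[TranscriptRecord]
    repeat_sequence: str | None = None

    def __post_init__(self):
        ids = [e.transcript_id for e in self.entries]
        if len(set(ids)) != len(ids):
            raise InvalidArgumentError("transcript ids are not unique")
        if any(len(e.sequence) == 0 for e in self.entries):
            raise InvalidArgumentError("empty transcript sequence")

    def __len__(self):
        return len(self.entries)

    @property
    def transcript_ids(self) -> list[str]:
        return [e.transcript_id for e in self.entries]

    def by_id(self, transcript_id: str) -> TranscriptRecord:
        return self._index()[transcript_id]

    def _index(self):
        if not hasattr(self, "_idx"):
            self._idx = {e.transcript_id: e for e in self.entries}
        return self._idx

    @property
    def gene_of(self) -> dict[str, str]:
        return {e.transcript_id: e.gene_symbol for e in self.entries}


@dataclass(frozen=True)
class ProbeRecord:
    probe_id: str
    probeset_id: str
    platform: str
    sequence: str
    source_transcript: str


@dataclass
class StudyDesign:
    """Sample design of one study.

    GA ranges are either a single ``(lo, hi)`` interval or a list of
    ``(lo, hi, n)`` groups summing to the sample count (dataset #1 samples
    cluster into mid-gestation and term groups rather than spanning one
    interval).
    """

    n_pe: int
    n_np: int
    ga_range_pe: tuple | list = (24.0, 39.0)
    ga_range_np: tuple | list = (14.0, 42.0)
    study_shift_sd: float = 0.5

    def __post_init__(self):
        if self.n_pe < 0 or self.n_np < 0 or self.n_pe + self.n_np == 0:
            raise InvalidArgumentError("study must have a positive sample count")
        for rng_, n in ((self.ga_range_pe, self.n_pe), (self.ga_range_np, self.n_np)):
            for lo, hi in _iter_intervals(rng_):
                if not (14.0 <= lo <= hi <= 42.0):
                    raise InvalidArgumentError(
                        f"GA interval ({lo}, {hi}) outside [14, 42] weeks"
                    )
            if isinstance(rng_, list) and sum(g[2] for g in rng_) != n:
                raise InvalidArgumentError("GA group sizes do not sum to sample count")


def _iter_intervals(rng_):
    if isinstance(rng_, list):
        for lo, hi, _n in rng_:
            yield lo, hi
    else:
        yield rng_


def default_study_designs() -> list[StudyDesign]:
    """Three-study design: 36 NP (27 mid-gestation weeks 14-24, 9 term weeks
    37-40); 12 PE + 11 NP in the third trimester; 37 PE + 58 NP with PE cases
    delivering earlier (weeks 25-39) than term controls (37-42).  The PE/GA
    confounding this induces is the central difficulty the pooled model with
    both covariates addresses."""
    return [
        StudyDesign(0, 36, ga_range_np=[(14.0, 24.0, 27), (37.0, 40.0, 9)]),
        StudyDesign(12, 11, ga_range_pe=(24.1, 37.6), ga_range_np=(24.7, 36.6)),
        StudyDesign(37, 58, ga_range_pe=(25.0, 39.0), ga_range_np=(37.0, 42.0)),
    ]


@dataclass
class SimulationConfig:
    n_transcripts: int = 2000
    seq_length: int = 250
    study_designs: list[StudyDesign] = field(default_factory=default_study_designs)
    beta_pe_sd: float = 0.5
    beta_ga_sd: float = 0.05       # per week of gestation
    frac_de_pe: float = 0.30
    frac_de_ga: float = 0.49
    d0: float = 4.0                # prior df of the residual-variance prior
    s0_sq: float = 0.25            # prior residual variance
    seed: int = 0

    def __post_init__(self):
        if not (0.0 <= self.frac_de_pe <= 1.0 and 0.0 <= self.frac_de_ga <= 1.0):
            raise InvalidArgumentError("DE fractions must lie in [0, 1]")
        if self.d0 <= 0 or self.s0_sq <= 0:
            raise InvalidArgumentError("variance prior requires d0 > 0 and s0_sq > 0")
        if self.n_transcripts < 1:
            raise InvalidArgumentError("n_transcripts must be >= 1")
        if not self.study_designs:
            raise InvalidArgumentError("at least one study design required")


@dataclass
class SyntheticTruth:
    """Ground truth recorded before noise is added."""

    transcript_ids: list[str]
    beta_pe: np.ndarray
    beta_ga: np.ndarray
    is_de_pe: np.ndarray
    is_de_ga: np.ndarray
    sigma2: np.ndarray

    @property
    def pi0_pe(self) -> float:
        return 1.0 - float(np.mean(self.is_de_pe))

    @property
    def pi0_ga(self) -> float:
        return 1.0 - float(np.mean(self.is_de_ga))

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "transcript_id": self.transcript_ids,
                "beta_pe": self.beta_pe,
                "beta_ga": self.beta_ga,
                "is_de_pe": self.is_de_pe.astype(int),
                "is_de_ga": self.is_de_ga.astype(int),
                "sigma2": self.sigma2,
            }
        )

    @classmethod
    def from_frame(cls, df: pd.DataFrame) -> "SyntheticTruth":
        return cls(
            transcript_ids=list(df["transcript_id"]),
            beta_pe=df["beta_pe"].to_numpy(float),
            beta_ga=df["beta_ga"].to_numpy(float),
            is_de_pe=df["is_de_pe"].to_numpy(bool),
            is_de_ga=df["is_de_ga"].to_numpy(bool),
            sigma2=df["sigma2"].to_numpy(float),
        )


# ---------------------------------------------------------------------------
# id scheme — shared between probe generation and expression matrices
# ---------------------------------------------------------------------------

def transcript_id(i: int) -> str:
    return f"TX{i:06d}"


def gene_symbol(i: int, n_transcripts: int) -> str:
    n_genes = max(1, round(n_transcripts / TRANSCRIPTS_PER_GENE))
    return f"GENE{i % n_genes:05d}"


def affy_probeset_id(i: int) -> str:
    return f"PS{i:06d}_at"


def ilmn_probe_id(i: int) -> str:
    return f"ILMN_{i:07d}"


# ---------------------------------------------------------------------------
# generation
# ---------------------------------------------------------------------------

def _rng(seed: int, *key: int) -> np.random.Generator:
    return np.random.default_rng(np.random.SeedSequence(seed, spawn_key=key))


def generate_catalog(
    n_transcripts: int,
    seq_length: int,
    seed: int,
    n_repeat_copies: int = 0,
    repeat_length: int = 60,
) -> TranscriptCatalog:
    """Generate a catalog of random transcripts with i.i.d. uniform bases.

    If ``n_repeat_copies > 0``, a single repeat motif of ``repeat_length`` is
    planted at a random position inside that many transcripts, emulating a
    high-copy repeat family from which promiscuous probes arise.
    """
    if n_transcripts < 1:
        raise InvalidArgumentError("n_transcripts must be >= 1")
    if seq_length < 60:
        raise InvalidArgumentError("seq_length must be >= 60")
    if n_repeat_copies > n_transcripts:
        raise InvalidArgumentError("more repeat copies than transcripts")

    rng = _rng(seed, 0)
    seqs = rng.integers(0, 4, size=(n_transcripts, seq_length))
    repeat = None
    if n_repeat_copies > 0:
        if repeat_length > seq_length:
            raise InvalidArgumentError("repeat longer than transcripts")
        repeat_arr = rng.integers(0, 4, size=repeat_length)
        carriers = rng.choice(n_transcripts, size=n_repeat_copies, replace=False)
        for t in carriers:
            pos = rng.integers(0, seq_length - repeat_length + 1)
            seqs[t, pos : pos + repeat_length] = repeat_arr
        repeat = "".join(BASES[repeat_arr])

    entries = [
        TranscriptRecord(
            transcript_id(i),
            gene_symbol(i, n_transcripts),
            "".join(BASES[seqs[i]]),
        )
        for i in range(n_transcripts)
    ]
    return TranscriptCatalog(entries, repeat_sequence=repeat)


def _mutate(seq: str, n_mismatches: int, rng: np.random.Generator) -> str:
    """Introduce exactly ``n_mismatches`` substitutions at distinct positions."""
    arr = list(seq)
    pos = rng.choice(len(arr), size=n_mismatches, replace=False)
    for p in pos:
        alternatives = [b for b in "ACGT" if b != arr[p]]
        arr[p] = alternatives[rng.integers(0, 3)]
    return "".join(arr)


def generate_probes(
    catalog: TranscriptCatalog,
    platform: str,
    probes_per_probeset: int = 11,
    seed: int = 0,
    mismatches_per_probe: int = 0,
    n_decoy_probes: int = 0,
) -> list[ProbeRecord]:
    """Emit a platform probe set targeting every transcript in the catalog.

    AFFY25 draws ``probes_per_probeset`` distinct 25-mers per transcript,
    grouped under one probeset id; ILMN50 emits a single 50-mer probe per
    transcript.  ``mismatches_per_probe`` substitutes that many bases in each
    probe (emulating stale annotation); decoy probes are drawn from the
    catalog's planted repeat and hit every repeat carrier.

    Transcripts shorter than the probe length are skipped with a warning.
    """
    if platform not in PROBE_LENGTH:
        raise InvalidArgumentError(f"unknown platform {platform!r}")
    if probes_per_probeset < 1:
        raise InvalidArgumentError("probes_per_probeset must be >= 1")
    if n_decoy_probes > 0 and catalog.repeat_sequence is None:
        raise InvalidArgumentError("decoy probes require a catalog with a repeat")

    plen = PROBE_LENGTH[platform]
    rng = _rng(seed, 1 if platform == AFFY25 else 2)
    probes: list[ProbeRecord] = []
    for i, entry in enumerate(catalog.entries):
        if len(entry.sequence) < plen:
            logger.warning(
                "transcript %s shorter than probe length %d; skipped",
                entry.transcript_id, plen,
            )
            continue
        n_positions = len(entry.sequence) - plen + 1
        if platform == AFFY25:
            k = min(probes_per_probeset, n_positions)
            starts = rng.choice(n_positions, size=k, replace=False)
            psid = affy_probeset_id(i)
            for j, start in enumerate(sorted(starts)):
                seq = entry.sequence[start : start + plen]
                if mismatches_per_probe:
                    seq = _mutate(seq, mismatches_per_probe, rng)
                probes.append(
                    ProbeRecord(f"{psid}:{j}", psid, platform, seq, entry.transcript_id)
                )
        else:
            start = rng.integers(0, n_positions)
            seq = entry.sequence[start : start + plen]
            if mismatches_per_probe:
                seq = _mutate(seq, mismatches_per_probe, rng)
            pid = ilmn_probe_id(i)
            probes.append(ProbeRecord(pid, pid, platform, seq, entry.transcript_id))

    for j in range(n_decoy_probes):
        rep = catalog.repeat_sequence
        if len(rep) < plen:
            raise InvalidArgumentError("repeat shorter than probe length")
        start = rng.integers(0, len(rep) - plen + 1)
        pid = f"DECOY_{platform}_{j:03d}"
        probes.append(ProbeRecord(pid, pid, platform, rep[start : start + plen], "repeat"))
    return probes


def _draw_ga(rng: np.random.Generator, spec_, n: int) -> np.ndarray:
    if isinstance(spec_, list):
        parts = [rng.uniform(lo, hi, size=cnt) for lo, hi, cnt in spec_]
        return np.concatenate(parts) if parts else np.empty(0)
    lo, hi = spec_
    return rng.uniform(lo, hi, size=n)


def generate_metadata(cfg: SimulationConfig) -> pd.DataFrame:
    """Sample table for all studies: sample_id, study (1-based), pe, ga_weeks."""
    rows = []
    for s, design in enumerate(cfg.study_designs, start=1):
        rng = _rng(cfg.seed, 10, s)
        ga_pe = _draw_ga(rng, design.ga_range_pe, design.n_pe)
        ga_np = _draw_ga(rng, design.ga_range_np, design.n_np)
        k = 0
        for pe, ga_vec in ((1, ga_pe), (0, ga_np)):
            for ga in ga_vec:
                rows.append((f"S{s}_{k:03d}", s, pe, round(float(ga), 1)))
                k += 1
    return pd.DataFrame(rows, columns=["sample_id", "study", "pe", "ga_weeks"])


def generate_studies(
    catalog: TranscriptCatalog, cfg: SimulationConfig
) -> tuple[list[pd.DataFrame], pd.DataFrame, SyntheticTruth]:
    """Simulate per-study expression matrices with known effects.

    Returns one features-by-samples DataFrame per study (the last study is
    indexed by 50-mer probe ids, all earlier studies by 25-mer probeset ids,
    matching the platform layout of the three source studies), the pooled
    sample metadata, and the ground truth.  Deterministic for a fixed
    ``cfg.seed``; the truth is recorded before noise is drawn.
    """
    n = len(catalog)
    rng_truth = _rng(cfg.seed, 20)

    is_de_pe = rng_truth.random(n) < cfg.frac_de_pe
    is_de_ga = rng_truth.random(n) < cfg.frac_de_ga
    beta_pe = np.where(is_de_pe, rng_truth.normal(0.0, cfg.beta_pe_sd, size=n), 0.0)
    beta_ga = np.where(is_de_ga, rng_truth.normal(0.0, cfg.beta_ga_sd, size=n), 0.0)
    sigma2 = cfg.s0_sq * cfg.d0 / rng_truth.chisquare(cfg.d0, size=n)
    mu = rng_truth.normal(7.0, 1.0, size=n)

    truth = SyntheticTruth(
        transcript_ids=catalog.transcript_ids,
        beta_pe=beta_pe,
        beta_ga=beta_ga,
        is_de_pe=is_de_pe,
        is_de_ga=is_de_ga,
        sigma2=sigma2,
    )

    metadata = generate_metadata(cfg)
    n_studies = len(cfg.study_designs)
    matrices: list[pd.DataFrame] = []
    for s, design in enumerate(cfg.study_designs, start=1):
        sub = metadata[metadata["study"] == s]
        rng = _rng(cfg.seed, 30, s)
        shift = rng.normal(0.0, design.study_shift_sd, size=n) if s > 1 else np.zeros(n)
        pe = sub["pe"].to_numpy(float)
        ga = sub["ga_weeks"].to_numpy(float)
        signal = (
            mu[:, None]
            + shift[:, None]
            + beta_pe[:, None] * pe[None, :]
            + beta_ga[:, None] * ga[None, :]
        )
        noise = rng.normal(0.0, 1.0, size=signal.shape) * np.sqrt(sigma2)[:, None]
        platform_ilmn = s == n_studies  # last study runs on the 50-mer platform
        feats = [
            ilmn_probe_id(i) if platform_ilmn else affy_probeset_id(i)
            for i in range(n)
        ]
        matrices.append(
            pd.DataFrame(signal + noise, index=feats, columns=list(sub["sample_id"]))
        )
    return matrices, metadata, truth


def default_pair_table(catalog: TranscriptCatalog) -> pd.DataFrame:
    """The one-pair-per-transcript table implied by the generator's id scheme
    (one probeset and one 50-mer probe per transcript), bypassing sequence
    matching.  Useful for calibration experiments where probe mapping itself
    is not under study."""
    n = len(catalog)
    return pd.DataFrame(
        {
            "affy_probeset_id": [affy_probeset_id(i) for i in range(n)],
            "ilmn_probe_id": [ilmn_probe_id(i) for i in range(n)],
            "transcript_id": catalog.transcript_ids,
            "gene_symbol": [e.gene_symbol for e in catalog.entries],
        }
    )


# ---------------------------------------------------------------------------
# I/O — FASTA for sequences, TSV for matrices and tables
# ---------------------------------------------------------------------------

def write_catalog_fasta(catalog: TranscriptCatalog, path) -> None:
    records = [
        SeqRecord(Seq(e.sequence), id=f"{e.transcript_id}|gene={e.gene_symbol}", description="")
        for e in catalog.entries
    ]
    SeqIO.write(records, str(path), "fasta")


def read_catalog_fasta(path) -> TranscriptCatalog:
    entries = []
    for rec in SeqIO.parse(str(path), "fasta"):
        tid, _, rest = rec.id.partition("|")
        gene = dict(kv.split("=", 1) for kv in rest.split("|") if "=" in kv).get("gene", tid)
        entries.append(TranscriptRecord(tid, gene, str(rec.seq).upper()))
    return TranscriptCatalog(entries)


def write_probes_fasta(probes: list[ProbeRecord], path) -> None:
    records = [
        SeqRecord(
            Seq(p.sequence),
            id=f"{p.probe_id}|probeset={p.probeset_id}|platform={p.platform}",
            description="",
        )
        for p in probes
    ]
    SeqIO.write(records, str(path), "fasta")


def read_probes_fasta(path) -> list[ProbeRecord]:
    probes = []
    for rec in SeqIO.parse(str(path), "fasta"):
        pid, _, rest = rec.id.partition("|")
        attrs = dict(kv.split("=", 1) for kv in rest.split("|") if "=" in kv)
        probes.append(
            ProbeRecord(
                pid,
                attrs.get("probeset", pid),
                attrs.get("platform", ""),
                str(rec.seq).upper(),
                attrs.get("source", ""),
            )
        )
    return probes


def write_matrix_tsv(matrix: pd.DataFrame, path) -> None:
    matrix.to_csv(path, sep="\t", index_label="feature_id", na_rep="NA")


def read_matrix_tsv(path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t", index_col="feature_id")


def write_metadata_tsv(metadata: pd.DataFrame, path) -> None:
    metadata.to_csv(path, sep="\t", index=False, na_rep="NA")


def read_metadata_tsv(path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t")
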