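"""FASTA / TSV / JSONL / YAML formats, run configuration, and the synthetic
transcript fixture generator.

All human-facing tabular files use 1-based coordinates (stated in their
header comments); in-memory coordinates are 0-based half-open throughout.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, asdict, field
from pathlib import Path

import numpy as np
import yaml
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

from .probing import ProbingRead
from .seqcore import RNA_ALPHABET, STANDARD_TABLE, Transcript, scan_motif

__all__ = [
    "read_fasta",
    "write_fasta",
    "load_transcript",
    "RunConfig",
    "FixtureSpec",
    "make_fixture",
    "write_reads_tsv",
    "read_reads_tsv",
]


def read_fasta(path) -> list[tuple[str, str]]:
    """Named sequences, uppercased and transcribed T->U.

    Invalid characters are reported with the file line on which they occur.
    """
    records = []
    for rec in SeqIO.parse(str(path), "fasta"):
        seq = str(rec.seq).upper().replace("T", "U")
        bad = set(seq) - RNA_ALPHABET
        if bad:
            ch = sorted(bad)[0]
            line_no = _find_line(path, ch)
            raise ValueError(
                f"{path}: invalid character {ch!r} in record {rec.id!r}"
                + (f" (line {line_no})" if line_no else "")
            )
        records.append((rec.id, seq))
    return records


def _find_line(path, ch: str) -> int | None:
    with open(path) as fh:
        for ln, line in enumerate(fh, 1):
            if line.startswith(">"):
                continue
            u = line.strip().upper().replace("T", "U")
            if ch in u:
                return ln
    return None


def write_fasta(records: list[tuple[str, str]], path) -> None:
    """Write (name, sequence) pairs wrapped at 60 columns."""
    recs = [
        SeqRecord(Seq(seq), id=name, description="") for name, seq in records
    ]
    SeqIO.write(recs, str(path), "fasta")


def load_transcript(fasta_path, config: dict | str | Path) -> Transcript:
    """Build a Transcript from a FASTA file plus a sidecar config.

    The config (dict, or path to YAML/JSON) must provide ``cds_start`` and
    ``cds_end`` (0-based half-open) and may provide ``motif`` and ``name``.
    """
    if not isinstance(config, dict):
        with open(config) as fh:
            config = yaml.safe_load(fh)
    records = read_fasta(fasta_path)
    name = config.get("name", records[0][0])
    seq = dict(records).get(name, records[0][1])
    return Transcript(
        seq=seq,
        cds_start=int(config["cds_start"]),
        cds_end=int(config["cds_end"]),
        motif=config.get("motif", "UGCAU"),
        name=name,
    )


@dataclass
class RunConfig:
    """Round-trippable record of everything a CLI run depends on."""

    command: str
    inputs: dict = field(default_factory=dict)
    cds_start: int | None = None
    cds_end: int | None = None
    motif: str = "UGCAU"
    model: dict = field(default_factory=dict)
    ga: dict = field(default_factory=dict)
    readsim: dict = field(default_factory=dict)
    outdir: str = "."
    seed: int = 0
    log_level: str = "INFO"

    def to_yaml(self, path) -> None:
        with open(path, "w") as fh:
            yaml.safe_dump(asdict(self), fh, sort_keys=True)

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        with open(path) as fh:
            return cls(**yaml.safe_load(fh))


@dataclass(frozen=True)
class FixtureSpec:
    """Recipe for a deterministic synthetic transcript.

    Stands in for the study organism's cyclin transcript (not printed in any
    public table): a random CDS with start/stop codons, random UTRs, and an
    exact number of embedded protein-binding motifs.
    """

    cds_codons: int = 100
    utr5_len: int = 60
    utr3_len: int = 60
    n_motifs: int = 5
    motif: str = "UGCAU"
    gc_bias: float = 0.5  # weight of G/C vs A/U when drawing UTR nucleotides
    seed: int = 0
    name: str = "fixture"

    def __post_init__(self):
        if self.cds_codons < 3:
            raise ValueError("CDS needs at least start + one codon + stop")
        if self.n_motifs * (len(self.motif) + 1) > self.utr5_len + self.utr3_len:
            raise ValueError("motifs do not fit in the UTRs")


def make_fixture(spec: FixtureSpec, max_tries: int = 500) -> Transcript:
    """Deterministic transcript with exactly ``spec.n_motifs`` motif sites.

    The CDS translates without internal stops (codons drawn from non-stop
    amino acids); motifs are planted in the UTRs and the whole transcript is
    resampled until the global motif count is exact.
    """
    rng = np.random.default_rng(spec.seed)
    aas = sorted(aa for aa in STANDARD_TABLE.degeneracy if aa not in "*MW")
    pw = np.array(
        [spec.gc_bias / 2, (1 - spec.gc_bias) / 2] * 2
    )  # G, A, C, U weights
    nts = np.array(list("GACU"))

    for _ in range(max_tries):
        codons = ["AUG"]
        for _i in range(spec.cds_codons - 2):
            aa = aas[int(rng.integers(len(aas)))]
            syn = STANDARD_TABLE.aa_to_codons[aa]
            codons.append(syn[int(rng.integers(len(syn)))])
        stops = sorted(STANDARD_TABLE.stop_codons)
        codons.append(stops[int(rng.integers(len(stops)))])
        cds = "".join(codons)

        utr5 = "".join(rng.choice(nts, spec.utr5_len, p=pw / pw.sum()))
        utr3 = "".join(rng.choice(nts, spec.utr3_len, p=pw / pw.sum()))

        # plant motifs at non-overlapping random offsets across the two UTRs
        utrs = [list(utr5), list(utr3)]
        slots = [
            (u, off)
            for u, utr in enumerate(utrs)
            for off in range(0, len(utr) - len(spec.motif) + 1)
        ]
        rng.shuffle(slots)
        placed: list[tuple[int, int]] = []
        for u, off in slots:
            if len(placed) == spec.n_motifs:
                break
            if all(
                u != pu or abs(off - poff) >= len(spec.motif)
                for pu, poff in placed
            ):
                utrs[u][off : off + len(spec.motif)] = list(spec.motif)
                placed.append((u, off))
        if len(placed) < spec.n_motifs:
            continue

        seq = "".join(utrs[0]) + cds + "".join(utrs[1])
        t = Transcript(
            seq,
            cds_start=spec.utr5_len,
            cds_end=spec.utr5_len + len(cds),
            motif=spec.motif,
            name=spec.name,
        )
        if len(scan_motif(t.seq, spec.motif)) == spec.n_motifs:
            return t
    raise RuntimeError(
        f"could not realize exactly {spec.n_motifs} motif occurrences "
        f"in {max_tries} attempts"
    )


_READS_HEADER = "# read_id\tstart\tend\tmodified_positions (1-based; interval 1-based inclusive-exclusive)"


def write_reads_tsv(reads: list[ProbingRead], path) -> None:
    with open(path, "w") as fh:
        fh.write(_READS_HEADER + "\n")
        for r in reads:
            mods = ",".join(str(p + 1) for p in r.modified_positions)
            fh.write(f"{r.read_id}\t{r.start + 1}\t{r.end + 1}\t{mods}\n")


def read_reads_tsv(path, transcript_seq: str) -> list[ProbingRead]:
    """Rebuild reads; unlisted adenosines in the interval are unmodified calls."""
    a_all = np.array(
        [i for i, c in enumerate(transcript_seq.upper().replace("T", "U")) if c == "A"]
    )
    reads = []
    with open(path) as fh:
        for line in fh:
            if line.startswith("#") or not line.strip():
                continue
            rid, s1, e1, mods = (line.rstrip("\n").split("\t") + [""])[:4]
            start, end = int(s1) - 1, int(e1) - 1
            modset = {int(x) - 1 for x in mods.split(",") if x}
            a_pos = [int(p) for p in a_all if start <= p < end]
            calls = [1 if p in modset else 0 for p in a_pos]
            reads.append(
                ProbingRead(rid, start, end, tuple(a_pos), tuple(calls))
            )
    return reads


def write_json(obj: dict, path) -> None:
    with open(path, "w") as fh:
        json.dump(obj, fh, indent=2, sort_keys=True)
        fh.write("\n")
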