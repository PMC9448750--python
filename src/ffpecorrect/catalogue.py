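"""Canonical SBS channel model and mutation-catalogue handling.

Single-base substitutions are described on the pyrimidine strand: every
variant is folded so that the mutated base is C or T, and is then placed
into one of 96 channels defined by the substitution type (C>A, C>G, C>T,
T>A, T>C, T>G) and the 5'/3' flanking bases.  Channel order follows the
COSMIC convention: substitution blocks in the order above, contexts
lexicographic by 5' then 3' base within each block.  All count vectors and
signature vectors in this package are indexed by that ordering.

The module also provides:

* construction of catalogues from variant records or VCF files,
* mutational-opportunity renormalization (projecting counts observed on a
  targeted panel onto whole-genome trinucleotide frequencies),
* the 80-channel (non-T>C) reduction used when batch-related T>C artefacts
  of unknown origin are suspected,
* masked cosine similarity,
* concordance/discordance classification of mutation tables across samples
  and the FFPE-only filtering rules used to isolate fixation artefacts.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Callable, Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

__all__ = [
    "SUBSTITUTIONS",
    "CHANNEL_LABELS",
    "CONTEXTS_32",
    "ChannelMask",
    "CT_MASK",
    "TC_MASK",
    "NON_TC_MASK",
    "ALL_MASK",
    "SbsChannel",
    "MutationRecord",
    "Catalogue",
    "OpportunityVector",
    "ChannelError",
    "ReferenceMismatchError",
    "UnsupportedVariantError",
    "UndefinedSimilarityError",
    "parse_channel",
    "classify_variant",
    "build_catalogue",
    "normalize_to_genome",
    "reduce_to_80c",
    "expand_from_80c",
    "cosine_similarity",
    "concordance_classify",
    "ffpe_only_filter",
    "concordant_wgs",
    "read_catalogue_tsv",
    "write_catalogue_tsv",
    "read_signature_matrix",
    "read_opportunity_tsv",
    "write_opportunity_tsv",
    "catalogue_from_vcf",
]

# --------------------------------------------------------------------------
# Channel model
# --------------------------------------------------------------------------

SUBSTITUTIONS: tuple[str, ...] = ("C>A", "C>G", "C>T", "T>A", "T>C", "T>G")
_BASES = "ACGT"
_COMPLEMENT = {"A": "T", "C": "G", "G": "C", "T": "A"}
_PYRIMIDINES = frozenset("CT")

#: the 96 canonical channel labels, COSMIC order
CHANNEL_LABELS: tuple[str, ...] = tuple(
    f"{five}[{sub}]{three}"
    for sub in SUBSTITUTIONS
    for five in _BASES
    for three in _BASES
)
_CHANNEL_INDEX: dict[str, int] = {lab: i for i, lab in enumerate(CHANNEL_LABELS)}

#: the 32 pyrimidine-centred trinucleotide contexts (C-centred block first)
CONTEXTS_32: tuple[str, ...] = tuple(
    f"{five}{centre}{three}"
    for centre in "CT"
    for five in _BASES
    for three in _BASES
)
_CONTEXT_INDEX: dict[str, int] = {ctx: i for i, ctx in enumerate(CONTEXTS_32)}

#: per-channel index into CONTEXTS_32
CHANNEL_CONTEXT_INDEX: np.ndarray = np.array(
    [
        (0 if CHANNEL_LABELS[i][2] == "C" else 16)
        + 4 * _BASES.index(CHANNEL_LABELS[i][0])
        + _BASES.index(CHANNEL_LABELS[i][6])
        for i in range(96)
    ]
)


class ChannelError(ValueError):
    """Malformed channel label or variant outside the SBS channel model."""


class ReferenceMismatchError(ChannelError):
    """Reported reference allele disagrees with the reference context."""


class UnsupportedVariantError(ChannelError):
    """Variant is not a single-base substitution."""


class UndefinedSimilarityError(ValueError):
    """Cosine similarity requested on an all-zero (masked) sub-vector."""


@dataclass(frozen=True)
class SbsChannel:
    """One of the 96 canonical single-base-substitution channels."""

    substitution: str
    five_prime: str
    three_prime: str

    def __post_init__(self) -> None:
        if self.substitution not in SUBSTITUTIONS:
            raise ChannelError(f"unknown substitution {self.substitution!r}")
        for b in (self.five_prime, self.three_prime):
            if b not in _BASES:
                raise ChannelError(f"invalid flanking base {b!r}")

    @property
    def label(self) -> str:
        return f"{self.five_prime}[{self.substitution}]{self.three_prime}"

    @property
    def index(self) -> int:
        return _CHANNEL_INDEX[self.label]

    @property
    def context(self) -> str:
        """Reference trinucleotide on the pyrimidine strand."""
        return f"{self.five_prime}{self.substitution[0]}{self.three_prime}"

    @property
    def context_index(self) -> int:
        return _CONTEXT_INDEX[self.context]


def parse_channel(label: str) -> SbsChannel:
    """Parse a canonical ``X[R>A]Y`` channel label.

    Raises :class:`ChannelError` for malformed labels, purine-centred
    substitutions, or identical ref/alt bases.
    """
    if (
        not isinstance(label, str)
        or len(label) != 7
        or label[1] != "["
        or label[3] != ">"
        or label[5] != "]"
    ):
        raise ChannelError(f"malformed channel label {label!r}")
    five, ref, alt, three = label[0], label[2], label[4], label[6]
    for b in (five, ref, alt, three):
        if b not in _BASES:
            raise ChannelError(f"invalid base in channel label {label!r}")
    if ref == alt:
        raise ChannelError(f"identical ref and alt in channel label {label!r}")
    if ref not in _PYRIMIDINES:
        raise ChannelError(
            f"purine-centred channel label {label!r}; use the pyrimidine strand"
        )
    return SbsChannel(f"{ref}>{alt}", five, three)


def _revcomp(seq: str) -> str:
    return "".join(_COMPLEMENT[b] for b in reversed(seq))


def classify_variant(
    chrom: str,
    pos: int,
    ref: str,
    alt: str,
    context_lookup: Callable[[str, int], str],
) -> SbsChannel:
    """Assign an SNV to its SBS channel, folding to the pyrimidine strand.

    ``context_lookup(chrom, pos)`` must return the reference trinucleotide
    centred at ``pos`` (1-based, forward strand).  Purine-centred variants
    are reverse-complemented before channel assignment.
    """
    ref, alt = str(ref).upper(), str(alt).upper()
    if len(ref) != 1 or len(alt) != 1 or ref not in _BASES or alt not in _BASES:
        raise UnsupportedVariantError(
            f"{chrom}:{pos} {ref}>{alt}: only single-base substitutions are supported"
        )
    if ref == alt:
        raise UnsupportedVariantError(f"{chrom}:{pos}: ref equals alt ({ref})")
    context = str(context_lookup(chrom, pos)).upper()
    if len(context) != 3 or any(b not in _BASES for b in context):
        raise ChannelError(f"{chrom}:{pos}: invalid reference context {context!r}")
    if context[1] != ref:
        raise ReferenceMismatchError(
            f"{chrom}:{pos}: reference allele {ref} disagrees with context "
            f"{context!r} (centre {context[1]})"
        )
    if ref not in _PYRIMIDINES:
        context = _revcomp(context)
        ref, alt = _COMPLEMENT[ref], _COMPLEMENT[alt]
    return SbsChannel(f"{ref}>{alt}", context[0], context[2])


# --------------------------------------------------------------------------
# Channel masks
# --------------------------------------------------------------------------


@dataclass(frozen=True)
class ChannelMask:
    """A named, sorted subset of the 96 channel indices."""

    name: str
    indices: tuple[int, ...]

    def __post_init__(self) -> None:
        idx = tuple(self.indices)
        if list(idx) != sorted(set(idx)) or (idx and (idx[0] < 0 or idx[-1] > 95)):
            raise ValueError("mask indices must be sorted, unique and in 0..95")

    def __len__(self) -> int:
        return len(self.indices)

    def apply(self, values: np.ndarray) -> np.ndarray:
        values = np.asarray(values)
        if values.shape[-1] != 96:
            raise ValueError("masks apply to 96-channel vectors")
        return values[..., list(self.indices)]


CT_MASK = ChannelMask("CT", tuple(range(32, 48)))
TC_MASK = ChannelMask("TC", tuple(range(64, 80)))
NON_TC_MASK = ChannelMask("NON_TC", tuple(i for i in range(96) if not 64 <= i < 80))
ALL_MASK = ChannelMask("ALL", tuple(range(96)))

#: position of the C>T block inside an 80-channel (non-T>C) vector; the
#: T>C block sits after C>T in the 96c order, so C>T indices are unchanged
CT_SLICE_80C = slice(32, 48)


# --------------------------------------------------------------------------
# Records and catalogues
# --------------------------------------------------------------------------


@dataclass
class MutationRecord:
    """One somatic SNV call, keyed by (chrom, pos, ref, alt)."""

    sample_id: str
    chrom: str
    pos: int
    ref: str
    alt: str
    channel: SbsChannel | None = None
    supporting_reads: int | None = None

    @property
    def key(self) -> tuple[str, int, str, str]:
        return (self.chrom, self.pos, self.ref, self.alt)


@dataclass
class Catalogue:
    """Per-sample mutation counts over the 96 canonical channels."""

    sample_id: str
    counts: np.ndarray
    metadata: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        counts = np.asarray(self.counts, dtype=float)
        if counts.shape != (96,):
            raise ValueError(f"catalogue must have 96 channels, got {counts.shape}")
        if np.any(counts < 0) or not np.all(np.isfinite(counts)):
            raise ValueError("catalogue counts must be finite and non-negative")
        self.counts = counts

    def total(self) -> float:
        return float(self.counts.sum())

    def to_profile(self) -> np.ndarray:
        """Counts normalized to a probability vector (error on empty)."""
        tot = self.total()
        if tot == 0:
            raise ValueError(f"catalogue {self.sample_id!r} is empty")
        return self.counts / tot

    def copy(self) -> "Catalogue":
        return Catalogue(self.sample_id, self.counts.copy(), dict(self.metadata))


def build_catalogue(
    records: Sequence[MutationRecord], sample_id: str | None = None
) -> Catalogue:
    """Tally classified mutation records into a 96-channel catalogue."""
    if sample_id is None:
        ids = {r.sample_id for r in records}
        if len(ids) > 1:
            raise ValueError(f"records span multiple samples: {sorted(ids)}")
        sample_id = next(iter(ids)) if ids else "<empty>"
    counts = np.zeros(96)
    for rec in records:
        if rec.channel is None:
            raise ValueError(f"record {rec.key} has no channel assigned")
        counts[rec.channel.index] += 1
    meta: dict = {}
    if not records:
        warnings.warn(f"building all-zero catalogue for {sample_id!r}", stacklevel=2)
        meta["empty_input"] = True
    return Catalogue(sample_id, counts, meta)


# --------------------------------------------------------------------------
# Opportunity renormalization
# --------------------------------------------------------------------------


@dataclass
class OpportunityVector:
    """Trinucleotide frequencies of a sequenced territory.

    32 pyrimidine-centred contexts (purine contexts folded before lookup),
    ordered as in :data:`CONTEXTS_32`.
    """

    freq: np.ndarray
    scope: str = "panel"

    def __post_init__(self) -> None:
        freq = np.asarray(self.freq, dtype=float)
        if freq.shape != (32,):
            raise ValueError("opportunity vector must have 32 contexts")
        if np.any(freq < 0) or not np.all(np.isfinite(freq)):
            raise ValueError("opportunities must be finite and non-negative")
        self.freq = freq

    def per_channel(self) -> np.ndarray:
        """Expand to a 96-vector by channel context."""
        return self.freq[CHANNEL_CONTEXT_INDEX]


def normalize_to_genome(
    cat: Catalogue, panel: OpportunityVector, genome: OpportunityVector
) -> np.ndarray:
    """Project panel counts onto genome trinucleotide context.

    Each channel count is weighted by ``genome[ctx] / panel[ctx]`` for its
    trinucleotide context and the result renormalized to a probability
    vector, making profiles from differently designed panels comparable.
    """
    panel_ch = panel.per_channel()
    genome_ch = genome.per_channel()
    bad = (panel_ch == 0) & (cat.counts > 0)
    if np.any(bad):
        labels = [CHANNEL_LABELS[i] for i in np.flatnonzero(bad)[:3]]
        raise ValueError(
            f"observed counts in contexts with zero panel opportunity: {labels}"
        )
    with np.errstate(divide="ignore", invalid="ignore"):
        weighted = np.where(cat.counts > 0, cat.counts * genome_ch / np.where(panel_ch == 0, 1.0, panel_ch), 0.0)
    tot = weighted.sum()
    if tot == 0:
        raise ValueError("projection of an empty catalogue is undefined")
    return weighted / tot


# --------------------------------------------------------------------------
# 80-channel reduction
# --------------------------------------------------------------------------


def reduce_to_80c(values: np.ndarray, renormalize: bool = True) -> np.ndarray:
    """Drop the 16 T>C channels; optionally rescale to sum 1.

    Channel order is otherwise preserved, so the C>T block keeps indices
    32..47 in the reduced vector.
    """
    values = np.asarray(values, dtype=float)
    if values.shape != (96,):
        raise ValueError("expected a 96-channel vector")
    out = NON_TC_MASK.apply(values)
    if renormalize:
        tot = out.sum()
        if tot == 0:
            raise ValueError("all mass on T>C channels; 80c renormalization undefined")
        out = out / tot
    return out


def expand_from_80c(values: np.ndarray) -> np.ndarray:
    """Re-embed an 80-channel vector into 96c with zeros at T>C."""
    values = np.asarray(values, dtype=float)
    if values.shape != (80,):
        raise ValueError("expected an 80-channel vector")
    out = np.zeros(96)
    out[list(NON_TC_MASK.indices)] = values
    return out


# --------------------------------------------------------------------------
# Cosine similarity
# --------------------------------------------------------------------------


def cosine_similarity(
    a: np.ndarray, b: np.ndarray, mask: ChannelMask | None = None
) -> float:
    """Cosine similarity on a channel subset.

    A zero sub-vector on either side raises
    :class:`UndefinedSimilarityError` rather than silently returning 0.
    """
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    if a.shape != b.shape:
        raise ValueError(f"shape mismatch: {a.shape} vs {b.shape}")
    if mask is not None:
        a, b = mask.apply(a), mask.apply(b)
    na, nb = np.linalg.norm(a), np.linalg.norm(b)
    if na == 0 or nb == 0:
        raise UndefinedSimilarityError("cosine undefined for a zero sub-vector")
    return float(a @ b / (na * nb))


# --------------------------------------------------------------------------
# Concordance analysis and FFPE-only filtering
# --------------------------------------------------------------------------

_KeyT = tuple[str, int, str, str]


def _dedup(records: Iterable[MutationRecord], label: str) -> list[MutationRecord]:
    seen: set[_KeyT] = set()
    out = []
    dups = 0
    for rec in records:
        if rec.key in seen:
            dups += 1
            continue
        seen.add(rec.key)
        out.append(rec)
    if dups:
        warnings.warn(f"{label}: removed {dups} duplicate mutation keys", stacklevel=3)
    return out


def _substitution_of(rec: MutationRecord) -> str:
    if rec.channel is not None:
        return rec.channel.substitution
    ref, alt = rec.ref.upper(), rec.alt.upper()
    if ref not in _PYRIMIDINES:
        ref, alt = _COMPLEMENT[ref], _COMPLEMENT[alt]
    return f"{ref}>{alt}"


def concordance_classify(
    tables: Mapping[str, Sequence[MutationRecord]],
) -> tuple[pd.DataFrame, pd.Series, pd.DataFrame]:
    """Flag mutations shared by ≥2 samples and summarise per substitution.

    Returns ``(per_mutation, per_substitution, pairwise)``:

    * ``per_mutation``: one row per (sample, mutation) with a ``concordant``
      flag — true iff the (chrom, pos, ref, alt) key occurs in at least two
      distinct samples;
    * ``per_substitution``: concordant fraction of mutation instances per
      substitution class;
    * ``pairwise``: for each sample pair, the fraction of the union of their
      mutations present in both.

    Recurrently shared mutations indicate SNP leakage or batch artefacts;
    randomly located fixation damage is expected to be mostly private.
    """
    clean = {sid: _dedup(recs, sid) for sid, recs in tables.items()}
    carriers: dict[_KeyT, set[str]] = {}
    for sid, recs in clean.items():
        for rec in recs:
            carriers.setdefault(rec.key, set()).add(sid)

    rows = []
    for sid, recs in clean.items():
        for rec in recs:
            rows.append(
                {
                    "sample_id": sid,
                    "chrom": rec.chrom,
                    "pos": rec.pos,
                    "ref": rec.ref,
                    "alt": rec.alt,
                    "substitution": _substitution_of(rec),
                    "concordant": len(carriers[rec.key]) >= 2,
                }
            )
    per_mutation = pd.DataFrame(
        rows,
        columns=["sample_id", "chrom", "pos", "ref", "alt", "substitution", "concordant"],
    )
    if len(per_mutation):
        per_substitution = per_mutation.groupby("substitution")["concordant"].mean()
    else:
        per_substitution = pd.Series(dtype=float, name="concordant")

    sids = sorted(clean)
    keysets = {sid: {r.key for r in clean[sid]} for sid in sids}
    pair_rows = []
    for i, a in enumerate(sids):
        for b in sids[i + 1 :]:
            union = keysets[a] | keysets[b]
            shared = keysets[a] & keysets[b]
            pair_rows.append(
                {
                    "sample_a": a,
                    "sample_b": b,
                    "n_shared": len(shared),
                    "n_union": len(union),
                    "concordance": len(shared) / len(union) if union else np.nan,
                }
            )
    pairwise = pd.DataFrame(
        pair_rows, columns=["sample_a", "sample_b", "n_shared", "n_union", "concordance"]
    )
    return per_mutation, per_substitution, pairwise


def ffpe_only_filter(
    ffpe_muts: Sequence[MutationRecord],
    ff_muts: Mapping[str, Sequence[MutationRecord]],
    normal_muts: Sequence[MutationRecord] = (),
    germline_sites: Iterable[_KeyT] = (),
    somatic_posterior: Mapping[_KeyT, float] | None = None,
) -> list[MutationRecord]:
    """Strip putative biological/germline calls, keeping fixation artefacts.

    A mutation is removed if it is (1) detected in *all* fresh-frozen
    samples, (2) detected in the matched normal, (3) has posterior
    probability of being somatic strictly above 0.90, or (4) is listed as a
    known germline site.  Input order is preserved.
    """
    ff_keysets = [{r.key for r in recs} for recs in ff_muts.values()]
    in_all_ff: set[_KeyT] = set.intersection(*ff_keysets) if ff_keysets else set()
    normal_keys = {r.key for r in normal_muts}
    germline = set(germline_sites)
    if somatic_posterior is None:
        warnings.warn(
            "no somatic posterior map supplied; skipping the posterior filter",
            stacklevel=2,
        )
        somatic_posterior = {}
    out = []
    for rec in ffpe_muts:
        k = rec.key
        if k in in_all_ff or k in normal_keys or k in germline:
            continue
        if somatic_posterior.get(k, 0.0) > 0.90:
            continue
        out.append(rec)
    return out


def concordant_wgs(
    mut_a: Sequence[MutationRecord],
    mut_b: Sequence[MutationRecord],
    min_reads: int = 5,
) -> list[MutationRecord]:
    """Variants present in both samples with ≥ ``min_reads`` support in each.

    Used to approximate the true somatic profile of a tumour from a pair of
    FFPE samples when no fresh-frozen material exists.
    """
    reads_b = {
        r.key: (r.supporting_reads if r.supporting_reads is not None else 0)
        for r in mut_b
    }
    out = []
    for rec in mut_a:
        ra = rec.supporting_reads if rec.supporting_reads is not None else 0
        if rec.key in reads_b and ra >= min_reads and reads_b[rec.key] >= min_reads:
            out.append(rec)
    return out


# --------------------------------------------------------------------------
# File formats
# --------------------------------------------------------------------------


def read_catalogue_tsv(path, sample_id: str | None = None) -> Catalogue:
    """Read a two-column ``MutationType<TAB><sample>`` catalogue TSV.

    Rows may be in any order; they are re-sorted to the canonical channel
    index.  With multiple sample columns, ``sample_id`` selects one.
    """
    df = pd.read_csv(path, sep="\t")
    type_col = df.columns[0]
    labels = df[type_col].astype(str)
    try:
        idx = labels.map(_CHANNEL_INDEX)
    except KeyError:  # pragma: no cover - map returns NaN instead
        idx = None
    if idx is None or idx.isna().any():
        bad = labels[~labels.isin(_CHANNEL_INDEX)].tolist()
        raise ChannelError(f"unknown channel labels in {path}: {bad[:3]}")
    if len(df) != 96 or idx.duplicated().any():
        raise ValueError(f"{path}: expected exactly the 96 canonical channels")
    if sample_id is None:
        if df.shape[1] != 2:
            raise ValueError(
                f"{path} has multiple sample columns; pass sample_id explicitly"
            )
        sample_id = df.columns[1]
    counts = np.zeros(96)
    counts[idx.to_numpy()] = df[sample_id].to_numpy(dtype=float)
    return Catalogue(str(sample_id), counts, {"source": str(path)})


def write_catalogue_tsv(cat: Catalogue, path) -> None:
    pd.DataFrame(
        {"MutationType": list(CHANNEL_LABELS), cat.sample_id: cat.counts}
    ).to_csv(path, sep="\t", index=False)


def read_signature_matrix(path, validate: bool = True) -> pd.DataFrame:
    """Read a COSMIC-layout signature TSV: ``Type`` column + one column per
    signature.  Returns a DataFrame indexed by channel label in canonical
    order; column sums are validated to ≈ 1.
    """
    df = pd.read_csv(path, sep="\t")
    type_col = df.columns[0]
    df = df.set_index(type_col)
    missing = [lab for lab in CHANNEL_LABELS if lab not in df.index]
    if missing:
        raise ChannelError(f"{path}: missing channels, e.g. {missing[:3]}")
    df = df.loc[list(CHANNEL_LABELS)]
    if validate:
        sums = df.sum(axis=0)
        off = sums[(sums - 1.0).abs() > 1e-3]
        if len(off):
            raise ValueError(f"{path}: signature columns do not sum to 1: {dict(off)}")
    return df.astype(float)


def read_opportunity_tsv(path, scope: str = "panel") -> OpportunityVector:
    """Read a ``Context<TAB>Frequency`` table with the 32 pyrimidine-centred
    trinucleotide contexts."""
    df = pd.read_csv(path, sep="\t")
    df = df.set_index(df.columns[0])
    missing = [c for c in CONTEXTS_32 if c not in df.index]
    if missing:
        raise ValueError(f"{path}: missing contexts, e.g. {missing[:3]}")
    freq = df.loc[list(CONTEXTS_32), df.columns[0]].to_numpy(dtype=float)
    return OpportunityVector(freq, scope=scope)


def write_opportunity_tsv(opp: OpportunityVector, path) -> None:
    pd.DataFrame({"Context": list(CONTEXTS_32), "Frequency": opp.freq}).to_csv(
        path, sep="\t", index=False
    )


def catalogue_from_vcf(vcf_path, fasta_path, sample_id: str | None = None) -> Catalogue:
    """Build a catalogue from the SNVs of a VCF plus an indexed FASTA.

    Non-SNV records are skipped with a warning tally; multi-allelic records
    contribute one count per single-base ALT.
    """
    import pysam
    from pyfaidx import Fasta

    fasta = Fasta(str(fasta_path), as_raw=True, sequence_always_upper=True)

    def context_lookup(chrom: str, pos: int) -> str:
        return str(fasta[chrom][pos - 2 : pos + 1])

    records: list[MutationRecord] = []
    skipped = 0
    with pysam.VariantFile(str(vcf_path)) as vcf:
        sid = sample_id or str(vcf_path)
        for rec in vcf.fetch() if vcf.index is not None else vcf:
            for alt in rec.alts or ():
                if len(rec.ref) != 1 or len(alt) != 1 or alt not in _BASES:
                    skipped += 1
                    continue
                channel = classify_variant(
                    rec.chrom, rec.pos, rec.ref, alt, context_lookup
                )
                records.append(
                    MutationRecord(sid, rec.chrom, rec.pos, rec.ref, alt, channel)
                )
    if skipped:
        warnings.warn(f"{vcf_path}: skipped {skipped} non-SNV alleles", stacklevel=2)
    return build_catalogue(records, sample_id=sid)
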