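"""Self-contained local alignment search with Karlin-Altschul statistics.

Two search modes mirror the classic translated/nucleotide BLAST workflow:

* nucleotide: exact-word seeds (default word size 11) on both strands,
  followed by an ungapped diagonal filter and full affine-gap Smith-Waterman
  restricted to a subject window around the seed cluster;
* translated: an amino-acid query against all six reading frames of a
  nucleotide database (default word size 3), with frame and strand-encoded
  nucleotide coordinates reported;
* protein: amino-acid query against an amino-acid database (used for
  ORF-to-ORF anchoring).

The gapped stage is an exact Smith-Waterman on the windowed subject, so the
only approximations relative to an unrestricted O(mn) alignment are the seed
requirement and the window bounds.  Every downstream stage consumes plain
tabular hits, so an external aligner's ``-outfmt 6`` output can substitute for
this module wholesale.

E-values use the raw search space ``m x n`` with no length correction; this
shifts absolute E-values slightly but preserves orderings, and the thresholds
used downstream are tiered orders of magnitude.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, replace
from typing import Iterable, Sequence

import numpy as np
from Bio.Align import substitution_matrices

from .io_formats import AlignmentHit, SeqRecord
from .seq_core import reverse_complement, translate

__all__ = [
    "ScoringScheme",
    "evalue",
    "smith_waterman",
    "LocalAlignment",
    "seed_extend_align",
    "translated_search",
    "NucleotideSearcher",
    "TranslatedDatabase",
    "ProteinDatabase",
]

_NEG = -(10**6)

# Published gapped Karlin-Altschul parameters for the default schemes,
# keyed by (scheme kind, *scoring parameters).
KARLIN_ALTSCHUL_TABLE: dict[tuple, tuple[float, float]] = {
    ("nucleotide", 1, -2, 5, 2): (1.28, 0.46),
    ("nucleotide", 1, -3, 5, 2): (1.37, 0.711),
    ("nucleotide", 2, -3, 5, 2): (0.550, 0.210),
    ("nucleotide", 5, -4, 10, 6): (0.163, 0.068),
    ("blosum62", 11, 1): (0.267, 0.041),
    ("blosum62", 0, 0): (0.318, 0.13),  # ungapped
}

_NT_ORDER = "ACGT"
_NT_CODE = {c: i for i, c in enumerate(_NT_ORDER)}
_NT_INVALID = 4

_BLOSUM62 = substitution_matrices.load("BLOSUM62")
_AA_ORDER = "".join(_BLOSUM62.alphabet)  # 'ARNDCQEGHILKMFPSTWYVBZX*'
_AA_CODE = {c: i for i, c in enumerate(_AA_ORDER)}
_AA_X = _AA_CODE["X"]
_AA_INVALID = len(_AA_ORDER)  # sentinel, never aligned


def _blosum62_matrix() -> np.ndarray:
    n = len(_AA_ORDER)
    mat = np.zeros((n + 1, n + 1), dtype=np.int32)
    for i, a in enumerate(_AA_ORDER):
        for j, b in enumerate(_AA_ORDER):
            mat[i, j] = int(_BLOSUM62[a, b])
    mat[n, :] = -4
    mat[:, n] = -4
    return mat


_BLOSUM62_NP = _blosum62_matrix()


def _nt_matrix(match: int, mismatch: int) -> np.ndarray:
    mat = np.full((5, 5), mismatch, dtype=np.int32)
    np.fill_diagonal(mat, match)
    mat[4, 4] = mismatch  # N never matches, not even itself
    return mat


def encode_nt(seq: str) -> np.ndarray:
    arr = np.frombuffer(seq.upper().encode("ascii"), dtype=np.uint8)
    out = np.full(arr.shape, _NT_INVALID, dtype=np.int8)
    for base, code in _NT_CODE.items():
        out[arr == ord(base)] = code
    return out


def encode_aa(seq: str) -> np.ndarray:
    out = np.full(len(seq), _AA_X, dtype=np.int8)
    for i, c in enumerate(seq.upper()):
        out[i] = _AA_CODE.get(c, _AA_X)
    return out


@dataclass(frozen=True)
class ScoringScheme:
    """Scoring parameters plus the Karlin-Altschul statistics they imply.

    ``gap_open``/``gap_extend`` are non-negative costs; a gap of length k
    costs ``gap_open + k * gap_extend``.
    """

    mode: str  # "nucleotide" | "translated" | "protein"
    match: int = 2
    mismatch: int = -3
    matrix_name: str = "BLOSUM62"
    gap_open: int = 5
    gap_extend: int = 2
    lam: float = 0.550
    K: float = 0.210
    word_size: int = 11

    def __post_init__(self) -> None:
        if self.lam <= 0 or self.K <= 0:
            raise ValueError("lambda and K must be positive")
        if self.gap_open < 0 or self.gap_extend < 0:
            raise ValueError("gap penalties must be non-negative")

    @classmethod
    def nucleotide(
        cls,
        match: int = 2,
        mismatch: int = -3,
        gap_open: int = 5,
        gap_extend: int = 2,
        word_size: int = 11,
        lam: float | None = None,
        K: float | None = None,
    ) -> "ScoringScheme":
        if lam is None or K is None:
            key = ("nucleotide", match, mismatch, gap_open, gap_extend)
            if key not in KARLIN_ALTSCHUL_TABLE:
                raise ValueError(
                    "no published Karlin-Altschul parameters for "
                    f"{key}; pass lam= and K= explicitly"
                )
            lam, K = KARLIN_ALTSCHUL_TABLE[key]
        return cls(
            mode="nucleotide",
            match=match,
            mismatch=mismatch,
            gap_open=gap_open,
            gap_extend=gap_extend,
            lam=lam,
            K=K,
            word_size=word_size,
        )

    @classmethod
    def translated(
        cls,
        matrix_name: str = "BLOSUM62",
        gap_open: int = 11,
        gap_extend: int = 1,
        word_size: int = 3,
        lam: float | None = None,
        K: float | None = None,
    ) -> "ScoringScheme":
        if matrix_name != "BLOSUM62":
            raise ValueError("only BLOSUM62 is bundled")
        if lam is None or K is None:
            key = ("blosum62", gap_open, gap_extend)
            if key not in KARLIN_ALTSCHUL_TABLE:
                raise ValueError(
                    "no published Karlin-Altschul parameters for "
                    f"{key}; pass lam= and K= explicitly"
                )
            lam, K = KARLIN_ALTSCHUL_TABLE[key]
        return cls(
            mode="translated",
            matrix_name=matrix_name,
            gap_open=gap_open,
            gap_extend=gap_extend,
            lam=lam,
            K=K,
            word_size=word_size,
        )

    @classmethod
    def protein(cls, **kwargs) -> "ScoringScheme":
        scheme = cls.translated(**kwargs)
        return replace(scheme, mode="protein")

    def score_matrix(self) -> np.ndarray:
        if self.mode == "nucleotide":
            return _nt_matrix(self.match, self.mismatch)
        return _BLOSUM62_NP

    def encode(self, seq: str) -> np.ndarray:
        if self.mode == "nucleotide":
            return encode_nt(seq)
        return encode_aa(seq)

    @property
    def invalid_code(self) -> int:
        return _NT_INVALID if self.mode == "nucleotide" else _AA_INVALID

    def bit_score(self, raw_score: float) -> float:
        return (self.lam * raw_score - math.log(self.K)) / math.log(2.0)


def evalue(bit_score: float, search_space: float) -> float:
    """Karlin-Altschul expectation: E = m*n * 2^(-bit score)."""
    if not math.isfinite(bit_score):
        raise ValueError("bit score must be finite")
    # exp2 underflows gracefully to 0.0 for very large bit scores
    try:
        return search_space * math.exp2(-bit_score)
    except OverflowError:
        return math.inf


# ---------------------------------------------------------------------------
# Exact affine-gap Smith-Waterman (row-vectorized)
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class LocalAlignment:
    """One local alignment in 0-based half-open coordinates."""

    score: int
    q_start: int
    q_end: int
    s_start: int
    s_end: int
    n_identical: int
    alignment_length: int
    mismatches: int
    gap_openings: int
    gap_columns: int

    @property
    def percent_identity(self) -> float:
        return 100.0 * self.n_identical / self.alignment_length


def smith_waterman(
    query: np.ndarray | str,
    subject: np.ndarray | str,
    scheme: ScoringScheme,
) -> LocalAlignment | None:
    """Unrestricted O(mn) local alignment with affine gaps.

    The horizontal-gap recurrence is solved per row with a running prefix
    maximum, which is exact for affine costs (a gap extending another gap in
    the same direction never beats the single longer gap it is part of).
    """
    qv = scheme.encode(query) if isinstance(query, str) else query
    sv = scheme.encode(subject) if isinstance(subject, str) else subject
    m, n = len(qv), len(sv)
    if m == 0 or n == 0:
        return None
    S = scheme.score_matrix()
    go, ge = scheme.gap_open, scheme.gap_extend
    goe = go + ge

    H = np.zeros((m + 1, n + 1), dtype=np.int32)
    Erow = np.full(n + 1, _NEG, dtype=np.int32)
    ge_j = ge * np.arange(1, n + 1, dtype=np.int32)
    best = 0
    best_ij = (0, 0)
    for i in range(1, m + 1):
        Hprev = H[i - 1]
        np.maximum(Erow - ge, Hprev - goe, out=Erow)
        diag = Hprev[:n] + S[qv[i - 1], sv]
        H0 = np.maximum(np.maximum(diag, Erow[1:]), 0)
        cum = np.maximum.accumulate(H0 + ge_j)
        Hrow = H0.copy()
        if n > 1:
            np.maximum(Hrow[1:], cum[:-1] - go - ge_j[1:], out=Hrow[1:])
        H[i, 1:] = Hrow
        row_best = int(Hrow.max())
        if row_best > best:
            best = row_best
            best_ij = (i, int(Hrow.argmax()) + 1)
    if best <= 0:
        return None

    # traceback on H alone; gap runs are recovered by testing full run costs
    i, j = best_ij
    n_id = n_mis = gap_open_count = gap_cols = aln_len = 0
    while i > 0 and j > 0 and H[i, j] > 0:
        s = int(S[qv[i - 1], sv[j - 1]])
        if H[i, j] == H[i - 1, j - 1] + s:
            aln_len += 1
            if qv[i - 1] == sv[j - 1] and qv[i - 1] != scheme.invalid_code:
                n_id += 1
            else:
                n_mis += 1
            i -= 1
            j -= 1
            continue
        moved = False
        for k in range(1, i + 1):
            if H[i, j] == H[i - k, j] - go - ge * k:
                aln_len += k
                gap_cols += k
                gap_open_count += 1
                i -= k
                moved = True
                break
        if moved:
            continue
        for k in range(1, j + 1):
            if H[i, j] == H[i, j - k] - go - ge * k:
                aln_len += k
                gap_cols += k
                gap_open_count += 1
                j -= k
                moved = True
                break
        if not moved:  # pragma: no cover - defensive
            break
    return LocalAlignment(
        score=best,
        q_start=i,
        q_end=best_ij[0],
        s_start=j,
        s_end=best_ij[1],
        n_identical=n_id,
        alignment_length=aln_len,
        mismatches=n_mis,
        gap_openings=gap_open_count,
        gap_columns=gap_cols,
    )


# ---------------------------------------------------------------------------
# Seeding
# ---------------------------------------------------------------------------

def _kmer_codes(enc: np.ndarray, k: int, base: int, invalid: int) -> np.ndarray:
    """Rolling k-mer codes; windows containing an invalid letter get code -1."""
    n = len(enc)
    if n < k:
        return np.empty(0, dtype=np.int64)
    codes = np.zeros(n - k + 1, dtype=np.int64)
    arr = enc.astype(np.int64)
    for t in range(k):
        codes = codes * base + arr[t : n - k + 1 + t]
    bad = (enc >= invalid).astype(np.int32)
    cbad = np.concatenate([[0], np.cumsum(bad)])
    window_bad = cbad[k:] - cbad[:-k]
    codes[window_bad > 0] = -1
    return codes


class _SeedIndex:
    """Exact k-mer index over a list of encoded sequences."""

    def __init__(self, encs: Sequence[np.ndarray], k: int, base: int, invalid: int):
        self.k = k
        self.base = base
        self.invalid = invalid
        self.encs = list(encs)
        sep = np.array([invalid], dtype=np.int8)
        parts: list[np.ndarray] = []
        starts: list[int] = []
        pos = 0
        for enc in self.encs:
            starts.append(pos)
            parts.append(enc)
            parts.append(sep)
            pos += len(enc) + 1
        self.starts = np.array(starts, dtype=np.int64)
        concat = np.concatenate(parts) if parts else np.empty(0, dtype=np.int8)
        codes = _kmer_codes(concat, k, base, invalid)
        valid = codes >= 0
        self._positions = np.nonzero(valid)[0].astype(np.int64)
        vcodes = codes[valid]
        order = np.argsort(vcodes, kind="stable")
        self._sorted_codes = vcodes[order]
        self._sorted_pos = self._positions[order]

    def lookup(self, q_codes: np.ndarray) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
        """Return (query positions, entry indices, entry-local positions)."""
        valid_q = np.nonzero(q_codes >= 0)[0]
        if len(valid_q) == 0 or len(self._sorted_codes) == 0:
            empty = np.empty(0, dtype=np.int64)
            return empty, empty, empty
        lo = np.searchsorted(self._sorted_codes, q_codes[valid_q], side="left")
        hi = np.searchsorted(self._sorted_codes, q_codes[valid_q], side="right")
        counts = hi - lo
        total = int(counts.sum())
        if total == 0:
            empty = np.empty(0, dtype=np.int64)
            return empty, empty, empty
        qpos = np.repeat(valid_q, counts)
        idx = np.concatenate([np.arange(a, b) for a, b in zip(lo, hi) if b > a])
        gpos = self._sorted_pos[idx]
        entry = np.searchsorted(self.starts, gpos, side="right") - 1
        local = gpos - self.starts[entry]
        return qpos.astype(np.int64), entry, local


def _best_diag_segment(
    qv: np.ndarray, sv: np.ndarray, diag: int, S: np.ndarray
) -> int:
    """Best contiguous ungapped segment score on one diagonal (Kadane)."""
    i0 = max(0, -diag)
    i1 = min(len(qv), len(sv) - diag)
    if i1 <= i0:
        return 0
    scores = S[qv[i0:i1], sv[i0 + diag : i1 + diag]].astype(np.int64)
    prefix = np.concatenate([[0], np.cumsum(scores)])
    return int(np.max(prefix[1:] - np.minimum.accumulate(prefix[:-1])))


@dataclass
class _SearchParams:
    band: int = 16  # diagonals within this distance form one seed cluster
    pad: int = 100  # extra subject bases beyond the query projection
    ungapped_min_nt: int = 16
    ungapped_min_aa: int = 40
    extension_margin_matches: int = 4  # nt clusters must beat a seed by this many matches

    def ungapped_min(self, scheme: "ScoringScheme", word_size: int) -> int:
        if scheme.mode == "nucleotide":
            # a lone exact seed scores match*word; demand real extension
            return max(
                self.ungapped_min_nt,
                scheme.match * (word_size + self.extension_margin_matches),
            )
        return self.ungapped_min_aa


def _search_encoded(
    q_enc: np.ndarray,
    index: _SeedIndex,
    scheme: ScoringScheme,
    params: _SearchParams,
) -> list[tuple[int, LocalAlignment]]:
    """Seeded search of one encoded query against an indexed database.

    Seeds are grouped into clusters of nearby diagonals per database entry.
    Amino-acid modes additionally require two seeds on one diagonal before a
    cluster is considered (word size 3 alone is unspecific); every surviving
    cluster must pass an ungapped best-segment filter before the windowed
    Smith-Waterman runs.  Returns (entry index, local alignment) pairs,
    unfiltered and undeduplicated.
    """
    S = scheme.score_matrix()
    q_codes = _kmer_codes(q_enc, index.k, index.base, index.invalid)
    qpos, entry, spos = index.lookup(q_codes)
    if len(qpos) == 0:
        return []
    diags = (spos - qpos).astype(np.int64)
    order = np.lexsort((diags, entry))
    e_s, d_s = entry[order], diags[order]

    if scheme.mode != "nucleotide":
        # two-hit requirement: >= 2 seed words on the same exact diagonal
        same = (np.diff(e_s) == 0) & (np.diff(d_s) == 0)
        keep = np.zeros(len(e_s), dtype=bool)
        keep[1:] |= same
        keep[:-1] |= same
        e_s, d_s = e_s[keep], d_s[keep]
        if len(e_s) == 0:
            return []

    new = np.ones(len(e_s), dtype=bool)
    new[1:] = (np.diff(e_s) != 0) | (np.diff(d_s) > params.band)
    bounds = np.nonzero(new)[0].tolist() + [len(e_s)]

    results: list[tuple[int, LocalAlignment]] = []
    threshold = params.ungapped_min(scheme, index.k)
    m = len(q_enc)
    for a, b in zip(bounds, bounds[1:]):
        e = int(e_s[a])
        sv = index.encs[e]
        cdiags = d_s[a:b]
        best_ungapped = max(
            _best_diag_segment(q_enc, sv, int(d), S) for d in np.unique(cdiags)
        )
        if best_ungapped < threshold:
            continue
        lo = max(0, int(cdiags.min()) - params.pad)
        hi = min(len(sv), int(cdiags.max()) + m + params.pad)
        aln = smith_waterman(q_enc, sv[lo:hi], scheme)
        if aln is None:
            continue
        aln = replace(aln, s_start=aln.s_start + lo, s_end=aln.s_end + lo)
        results.append((e, aln))
    return results


def _dedupe(hits: list[AlignmentHit]) -> list[AlignmentHit]:
    """Drop hits that substantially duplicate a higher-scoring one on the same
    subject and strand (>=50% reciprocal span overlap)."""
    hits = sorted(hits, key=lambda h: (-h.bit_score, h.s_start, h.q_start))
    kept: list[AlignmentHit] = []
    for h in hits:
        hs = h.subject_span()
        duplicate = False
        for k in kept:
            if k.subject_id != h.subject_id:
                continue
            if k.subject_on_minus_strand != h.subject_on_minus_strand:
                continue
            if (k.frame is None) != (h.frame is None) or k.frame != h.frame:
                continue
            ks = k.subject_span()
            s_ov = min(hs[1], ks[1]) - max(hs[0], ks[0]) + 1
            q_ov = min(h.q_end, k.q_end) - max(h.q_start, k.q_start) + 1
            if s_ov > 0.5 * (hs[1] - hs[0] + 1) and q_ov > 0.5 * (
                h.q_end - h.q_start + 1
            ):
                duplicate = True
                break
        if not duplicate:
            kept.append(h)
    return kept


def _to_hit(
    aln: LocalAlignment,
    query_id: str,
    subject_id: str,
    scheme: ScoringScheme,
    search_space: float,
    minus: bool = False,
    query_len: int = 0,
    frame: int | None = None,
) -> AlignmentHit:
    bits = scheme.bit_score(aln.score)
    if minus:
        # alignment was computed on the reverse-complemented query; report
        # ascending query coordinates and a descending subject span
        q_start = query_len - aln.q_end + 1
        q_end = query_len - aln.q_start
        s_start, s_end = aln.s_end, aln.s_start + 1
    else:
        q_start, q_end = aln.q_start + 1, aln.q_end
        s_start, s_end = aln.s_start + 1, aln.s_end
    return AlignmentHit(
        query_id=query_id,
        subject_id=subject_id,
        percent_identity=round(aln.percent_identity, 2),
        alignment_length=aln.alignment_length,
        mismatches=aln.mismatches,
        gap_openings=aln.gap_openings,
        q_start=q_start,
        q_end=q_end,
        s_start=s_start,
        s_end=s_end,
        e_value=evalue(bits, search_space),
        bit_score=round(bits, 1),
        frame=frame,
    )


# ---------------------------------------------------------------------------
# Searchers
# ---------------------------------------------------------------------------

class NucleotideSearcher:
    """Seeded nucleotide search of many queries against one subject sequence."""

    def __init__(
        self,
        subject: SeqRecord,
        scheme: ScoringScheme | None = None,
        word_size: int | None = None,
        evalue_cutoff: float = 10.0,
        params: _SearchParams | None = None,
    ):
        self.scheme = scheme or ScoringScheme.nucleotide()
        word = word_size or self.scheme.word_size
        if word < 4:
            raise ValueError("nucleotide word size must be >= 4")
        self.subject = subject
        self.evalue_cutoff = evalue_cutoff
        self.params = params or _SearchParams()
        enc = self.scheme.encode(subject.sequence)
        self.index = _SeedIndex([enc], word, base=5, invalid=_NT_INVALID)

    def search(self, query: SeqRecord) -> list[AlignmentHit]:
        if not query.sequence or not self.subject.sequence:
            return []
        m = len(query.sequence)
        space = float(m) * len(self.subject.sequence)
        hits: list[AlignmentHit] = []
        for minus, seq in ((False, query.sequence), (True, reverse_complement(query.sequence))):
            enc = self.scheme.encode(seq)
            for _, aln in _search_encoded(enc, self.index, self.scheme, self.params):
                hit = _to_hit(
                    aln,
                    query.id,
                    self.subject.id,
                    self.scheme,
                    space,
                    minus=minus,
                    query_len=m,
                )
                if hit.e_value <= self.evalue_cutoff:
                    hits.append(hit)
        return _dedupe(hits)


def seed_extend_align(
    query: SeqRecord,
    subject: SeqRecord,
    scheme: ScoringScheme | None = None,
    word_size: int | None = None,
    evalue_cutoff: float = 10.0,
) -> list[AlignmentHit]:
    """Seeded local alignment of one query/subject pair (both strands for
    nucleotide mode)."""
    scheme = scheme or ScoringScheme.nucleotide()
    if scheme.mode == "nucleotide":
        return NucleotideSearcher(
            subject, scheme, word_size, evalue_cutoff=evalue_cutoff
        ).search(query)
    db = ProteinDatabase([subject], scheme, word_size, evalue_cutoff=evalue_cutoff)
    return db.search(query)


class ProteinDatabase:
    """Seeded protein-vs-protein search against a set of protein sequences."""

    def __init__(
        self,
        subjects: Sequence[SeqRecord],
        scheme: ScoringScheme | None = None,
        word_size: int | None = None,
        evalue_cutoff: float = 10.0,
        params: _SearchParams | None = None,
    ):
        self.scheme = scheme or ScoringScheme.protein()
        word = word_size or self.scheme.word_size
        if word < 2:
            raise ValueError("protein word size must be >= 2")
        self.subjects = list(subjects)
        self.evalue_cutoff = evalue_cutoff
        self.params = params or _SearchParams()
        encs = [self.scheme.encode(s.sequence) for s in self.subjects]
        self.index = _SeedIndex(encs, word, base=_AA_INVALID + 1, invalid=_AA_INVALID)

    def search(self, query: SeqRecord) -> list[AlignmentHit]:
        if not query.sequence:
            return []
        enc = self.scheme.encode(query.sequence)
        hits: list[AlignmentHit] = []
        for e, aln in _search_encoded(enc, self.index, self.scheme, self.params):
            subj = self.subjects[e]
            space = float(len(query.sequence)) * len(subj.sequence)
            hit = _to_hit(aln, query.id, subj.id, self.scheme, space)
            if hit.e_value <= self.evalue_cutoff:
                hits.append(hit)
        return _dedupe(hits)


class TranslatedDatabase:
    """Protein query against all six reading frames of a nucleotide database.

    Frames 1..3 are forward-strand offsets 0..2; frames -1..-3 are the same
    offsets on the reverse complement.  Reported subject coordinates are
    nucleotide positions on the forward strand, with ``s_start > s_end``
    encoding minus-frame hits.
    """

    def __init__(
        self,
        subjects: Sequence[SeqRecord],
        scheme: ScoringScheme | None = None,
        word_size: int | None = None,
        evalue_cutoff: float = 10.0,
        params: _SearchParams | None = None,
    ):
        self.scheme = scheme or ScoringScheme.translated()
        word = word_size or self.scheme.word_size
        self.subjects = list(subjects)
        self.evalue_cutoff = evalue_cutoff
        self.params = params or _SearchParams()
        self._meta: list[tuple[int, int]] = []  # (subject index, frame)
        encs: list[np.ndarray] = []
        for si, rec in enumerate(self.subjects):
            for frame in (1, 2, 3, -1, -2, -3):
                prot = translate(rec.sequence, frame)
                encs.append(self.scheme.encode(prot))
                self._meta.append((si, frame))
        self.index = _SeedIndex(encs, word, base=_AA_INVALID + 1, invalid=_AA_INVALID)

    def _nt_span(
        self, frame: int, aa_start0: int, aa_end0: int, nt_len: int
    ) -> tuple[int, int]:
        """Map a 0-based half-open aa span in a frame translation to 1-based
        nucleotide coordinates on the forward strand (descending for minus)."""
        off = abs(frame) - 1
        p1 = off + 3 * aa_start0 + 1  # first base, frame-local, 1-based
        p2 = off + 3 * aa_end0  # last base
        if frame > 0:
            return p1, p2
        return nt_len - p1 + 1, nt_len - p2 + 1

    def search(self, protein: SeqRecord) -> list[AlignmentHit]:
        if not protein.sequence:
            return []
        enc = self.scheme.encode(protein.sequence)
        hits: list[AlignmentHit] = []
        for e, aln in _search_encoded(enc, self.index, self.scheme, self.params):
            si, frame = self._meta[e]
            subj = self.subjects[si]
            nt_len = len(subj.sequence)
            s_start, s_end = self._nt_span(frame, aln.s_start, aln.s_end, nt_len)
            bits = self.scheme.bit_score(aln.score)
            space = float(len(protein.sequence)) * nt_len
            hit = AlignmentHit(
                query_id=protein.id,
                subject_id=subj.id,
                percent_identity=round(aln.percent_identity, 2),
                alignment_length=aln.alignment_length,
                mismatches=aln.mismatches,
                gap_openings=aln.gap_openings,
                q_start=aln.q_start + 1,
                q_end=aln.q_end,
                s_start=s_start,
                s_end=s_end,
                e_value=evalue(bits, space),
                bit_score=round(bits, 1),
                frame=frame,
            )
            if hit.e_value <= self.evalue_cutoff:
                hits.append(hit)
        return _dedupe(hits)


def translated_search(
    protein: SeqRecord,
    nucleotide: SeqRecord,
    scheme: ScoringScheme | None = None,
    word_size: int = 3,
    evalue_cutoff: float = 10.0,
) -> list[AlignmentHit]:
    """One protein against the six frames of one nucleotide sequence."""
    db = TranslatedDatabase(
        [nucleotide], scheme, word_size, evalue_cutoff=evalue_cutoff
    )
    return db.search(protein)
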