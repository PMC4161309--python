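"""Protein local alignment with BLAST-like statistics.

Striped local alignment (BLOSUM62, affine gaps) via Bio.Align, with
Karlin–Altschul E-values under a fixed gapped-BLOSUM62 parameterization
(lambda = 0.267, K = 0.041, the standard values for open 11 / extend 1).
Used for the all-vs-all ortholog search, the translated (six-frame) contig
screens, and completeness estimation.
"""

from __future__ import annotations

import math
from functools import lru_cache

from Bio import Align
from Bio.Align import substitution_matrices
from Bio.Seq import Seq

KA_LAMBDA = 0.267
KA_K = 0.041


@lru_cache(maxsize=1)
def _aligner() -> Align.PairwiseAligner:
    aligner = Align.PairwiseAligner()
    aligner.mode = "local"
    aligner.substitution_matrix = substitution_matrices.load("BLOSUM62")
    aligner.open_gap_score = -11
    aligner.extend_gap_score = -1
    return aligner


def evalue(score: float, m: int, n: int) -> float:
    """Karlin–Altschul expected number of chance hits at this raw score."""
    return KA_K * m * n * math.exp(-KA_LAMBDA * score)


def score_threshold(m: int, n: int, e_cutoff: float = 1e-5) -> float:
    """Raw score at which E(score) == e_cutoff for search space m x n."""
    return math.log(KA_K * m * n / e_cutoff) / KA_LAMBDA


def align_pair(query: str, subject: str):
    """Best local alignment of two proteins.

    Returns a dict with raw ``score``, percent ``identity`` over aligned
    columns (gaps excluded), per-sequence ``query_coverage`` and
    ``subject_coverage`` (aligned footprint / length), the number of aligned
    columns, and the Karlin–Altschul ``evalue`` — or None when no positive-
    scoring alignment exists.
    """
    query = query.replace("*", "").replace("X", "A")
    subject = subject.replace("*", "").replace("X", "A")
    if not query or not subject:
        return None
    alns = _aligner().align(query, subject)
    if len(alns) == 0 or alns.score <= 0:
        return None
    aln = alns[0]
    blocks_q, blocks_s = aln.aligned
    matches = 0
    cols = 0
    for (q0, q1), (s0, s1) in zip(blocks_q, blocks_s):
        for a, b in zip(query[q0:q1], subject[s0:s1]):
            cols += 1
            if a == b:
                matches += 1
    if cols == 0:
        return None
    q_span = blocks_q[-1][1] - blocks_q[0][0]
    s_span = blocks_s[-1][1] - blocks_s[0][0]
    return {
        "score": float(aln.score),
        "identity": 100.0 * matches / cols,
        "aligned_columns": cols,
        "query_coverage": q_span / len(query),
        "subject_coverage": s_span / len(subject),
        "evalue": evalue(aln.score, len(query), len(subject)),
    }


def six_frame_fragments(nt_seq: str, min_len: int = 20):
    """ORF-agnostic six-frame translation fragments (split at stops)."""
    fragments = []
    rc = str(Seq(nt_seq).reverse_complement())
    for strand_seq in (nt_seq, rc):
        for frame in range(3):
            sub = strand_seq[frame:]
            sub = sub[: len(sub) - len(sub) % 3]
            if not sub:
                continue
            prot = str(Seq(sub).translate())
            for piece in prot.split("*"):
                if len(piece) >= min_len:
                    fragments.append(piece)
    return fragments


def translated_hit(nt_seq: str, panel, e_cutoff: float = 1e-5,
                   min_fragment: int = 20) -> bool:
    """Does any six-frame fragment of ``nt_seq`` hit a panel protein at E <= cutoff?

    ``panel`` is an iterable of protein sequences.  An exact-substring
    pre-check short-circuits the alignment for identical copies.
    """
    fragments = six_frame_fragments(nt_seq, min_fragment)
    for frag in fragments:
        for prot in panel:
            if len(frag) >= 30 and (frag[:30] in prot or prot[:30] in frag):
                return True
            hit = align_pair(frag, prot)
            if hit is not None and hit["evalue"] <= e_cutoff:
                return True
    return False


class PanelIndex:
    """Peptide k-mer index over a protein panel for fast translated screens.

    Candidate panel members sharing a ``k``-mer with a translation fragment
    are confirmed by local alignment; fragments with no shared k-mer are
    rejected without aligning.  At the divergences this package targets a
    true homolog virtually always shares an exact 5-mer.
    """

    def __init__(self, panel, k: int = 5):
        self.k = k
        self.panel = [p.replace("*", "") for p in panel]
        self.index = {}
        for pid, prot in enumerate(self.panel):
            for i in range(len(prot) - k + 1):
                self.index.setdefault(prot[i : i + k], set()).add(pid)

    def __len__(self):
        return len(self.panel)

    def _candidates(self, fragment: str):
        out = set()
        for i in range(len(fragment) - self.k + 1):
            out |= self.index.get(fragment[i : i + self.k], set())
        return out

    def has_translated_hit(self, nt_seq: str, e_cutoff: float = 1e-5,
                           min_fragment: int = 20) -> bool:
        for frag in six_frame_fragments(nt_seq, min_fragment):
            for pid in self._candidates(frag):
                hit = align_pair(frag, self.panel[pid])
                if hit is not None and hit["evalue"] <= e_cutoff:
                    return True
        return False


def global_protein_alignment(p1: str, p2: str):
    """Global BLOSUM62 alignment of two proteins as gapped strings."""
    aligner = Align.PairwiseAligner()
    aligner.mode = "global"
    aligner.substitution_matrix = substitution_matrices.load("BLOSUM62")
    aligner.open_gap_score = -11
    aligner.extend_gap_score = -1
    p1c = p1.replace("*", "")
    p2c = p2.replace("*", "")
    aln = aligner.align(p1c, p2c)[0]
    blocks_a, blocks_b = aln.aligned
    out_a, out_b = [], []
    pa = pb = 0
    for (a0, a1), (b0, b1) in zip(blocks_a, blocks_b):
        out_a.append(p1c[pa:a0])
        out_b.append("-" * (a0 - pa))
        out_a.append("-" * (b0 - pb))
        out_b.append(p2c[pb:b0])
        out_a.append(p1c[a0:a1])
        out_b.append(p2c[b0:b1])
        pa, pb = a1, b1
    out_a.append(p1c[pa:])
    out_b.append("-" * (len(p1c) - pa))
    out_a.append("-" * (len(p2c) - pb))
    out_b.append(p2c[pb:])
    return "".join(out_a), "".join(out_b)
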