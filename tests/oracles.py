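"""Independent reference implementations used only to cross-check the
package: a position-by-position score evaluator and a per-base sliding
window scan.  Deliberately naive and written separately from the library
code paths they validate."""

from __future__ import annotations

COMPLEMENT = {"A": "T", "C": "G", "G": "C", "T": "A", "N": "N"}


def revcomp(seq: str) -> str:
    return "".join(COMPLEMENT[c] for c in reversed(seq))


def naive_score(mask, s_values, seg_lengths=(5, 5, 10)):
    """Evaluate the segmented score rule directly: +s_i per match, -s_i/2
    per isolated mismatch, -s_i per consecutive-run member, boundary runs
    charged the mean of the spanned segments' s values."""
    seg = []
    for i, l in enumerate(seg_lengths):
        seg.extend([i] * l)
    score = 0.0
    i = 0
    n = len(mask)
    while i < n:
        if not mask[i]:
            score += s_values[seg[i]]
            i += 1
            continue
        j = i
        while j < n and mask[j]:
            j += 1
        if j - i == 1:
            score -= s_values[seg[i]] / 2.0
        else:
            spanned = sorted({seg[p] for p in range(i, j)})
            score -= (sum(s_values[t] for t in spanned) / len(spanned)) * (j - i)
        i = j
    return score


def sliding_window_scan(genome, guide, budget, admit_nng=False):
    """Brute-force candidate enumeration: slide a 20-nt window over every
    position of both strands, count mismatches character by character, and
    keep windows with an admissible PAM.  Returns a set of
    (chrom, start, strand, n_mismatches)."""

    def ok_pam(p):
        if len(p) != 3:
            return False
        if p[1] == "G" and p[2] == "G":
            return True
        return admit_nng and p[2] == "G" and p[1] != "G"

    def hamming(a, b):
        return sum(1 for x, y in zip(a, b) if x != y)

    hits = set()
    for chrom, seq in genome.items():
        seq = seq.upper()
        L = len(seq)
        for i in range(L - 19):
            # plus strand
            if i + 23 <= L and ok_pam(seq[i + 20 : i + 23]):
                d = hamming(guide, seq[i : i + 20])
                if d <= budget:
                    hits.add((chrom, i, "+", d))
            # minus strand: protospacer [i, i+20), PAM [i-3, i) revcomp'd
            if i >= 3:
                pam = revcomp(seq[i - 3 : i])
                if ok_pam(pam):
                    d = hamming(guide, revcomp(seq[i : i + 20]))
                    if d <= budget:
                        hits.add((chrom, i, "-", d))
    return hits


def per_base_bin_counts(peak_sets, chrom_len, chrom, bin_width):
    """Per-bin cell-type counts computed the slow way: mark every covered
    base per file, then collapse to bins."""
    n_bins = (chrom_len + bin_width - 1) // bin_width
    counts = [0] * n_bins
    for peaks in peak_sets:
        covered = [False] * chrom_len
        for c, s, e in peaks:
            if c != chrom:
                continue
            for b in range(max(s, 0), min(e, chrom_len)):
                covered[b] = True
        for idx in range(n_bins):
            lo, hi = idx * bin_width, min((idx + 1) * bin_width, chrom_len)
            if any(covered[lo:hi]):
                counts[idx] += 1
    return {i: x for i, x in enumerate(counts) if x > 0}
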