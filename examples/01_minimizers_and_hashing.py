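"""Minimizer selection and integer hashing on a short sequence.

Every k-mer is canonicalised (the lexicographically smaller of itself
and its reverse complement) and hashed to a base-4 integer that
preserves lexicographic order.  One minimizer — the smallest canonical
k-mer — is kept per window of k consecutive k-mers, plus shorter
end-anchored windows, which compresses the k-mer content of a sequence
several-fold while staying strand-insensitive.
"""

import numpy as np

import mnbc

k = 7
rng = np.random.default_rng(0)
seq = "".join(np.array(list("ACGT"))[rng.integers(4, size=120)])

print(f"sequence ({len(seq)} bp): {seq}")
print(f"hash('GATTACA') = {mnbc.hash_kmer('GATTACA')}  "
      f"(base-4 numeral of the k-mer, A<C<G<T)")
print(f"unhash -> {mnbc.unhash_kmer(mnbc.hash_kmer('GATTACA'), 7)!r}")
print(f"canonical('GATTACA') = {mnbc.canonical_kmer('GATTACA')!r} "
      f"(vs revcomp {mnbc.reverse_complement('GATTACA')!r})")

mins = mnbc.extract_minimizers(seq, k)
rc_mins = mnbc.extract_minimizers(mnbc.reverse_complement(seq), k)
n_positions = len(seq) - k + 1

print(f"\nk={k}: {n_positions} k-mer positions -> {len(mins)} unique minimizers "
      f"({n_positions / len(mins):.1f}x compression)")
print(f"strand invariant: {mins == rc_mins}")
print("smallest five minimizers:",
      [mnbc.unhash_kmer(h, k) for h in sorted(mins)[:5]])
# The compression factor is what lets a whole reference collection of
# genome sketches sit in memory during classification.
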