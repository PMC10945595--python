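"""Independent NG86 counting oracle: direct enumeration from an inline
genetic-code table (kept separate from the package's implementation)."""

from __future__ import annotations

import itertools

_BASES = "TCAG"
_AAS = "FFLLSSSSYY**CC*WLLLLPPPPHHQQRRRRIIIMTTTTNNKKSSRRVVVVAAAADDEEGGGG"
CODE = {
    a + b + c: _AAS[16 * i + 4 * j + k]
    for i, a in enumerate(_BASES)
    for j, b in enumerate(_BASES)
    for k, c in enumerate(_BASES)
}
SENSE = sorted(c for c, aa in CODE.items() if aa != "*")
STOPS = sorted(c for c, aa in CODE.items() if aa == "*")


def oracle_sites(codon):
    """Potential synonymous/nonsynonymous sites by neighbor enumeration
    (stop neighbors excluded from the per-position denominator)."""
    s = 0.0
    for pos in range(3):
        syn = tot = 0
        for nt in "ACGT":
            if nt == codon[pos]:
                continue
            nb = codon[:pos] + nt + codon[pos + 1:]
            if CODE[nb] == "*":
                continue
            tot += 1
            if CODE[nb] == CODE[codon]:
                syn += 1
        if tot:
            s += syn / tot
    return s, 3 - s


def oracle_path_counts(a, b):
    """Observed Sd/Sn averaged over stop-free substitution pathways (all
    pathways, with stop steps nonsynonymous, if none is stop-free)."""
    diff = [i for i in range(3) if a[i] != b[i]]
    if not diff:
        return 0.0, 0.0
    clean, dirty = [], []
    for order in itertools.permutations(diff):
        cur, syn, nsyn, stop = a, 0, 0, False
        for pos in order:
            nxt = cur[:pos] + b[pos] + cur[pos + 1:]
            if CODE[nxt] == "*":
                stop = True
            if CODE[cur] != "*" and CODE[nxt] != "*" and CODE[cur] == CODE[nxt]:
                syn += 1
            else:
                nsyn += 1
            cur = nxt
        (dirty if stop else clean).append((syn, nsyn))
    paths = clean or dirty
    return (sum(p[0] for p in paths) / len(paths),
            sum(p[1] for p in paths) / len(paths))
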