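"""Motif-x-style iterative enrichment of phosphosite windows.

Phosphopeptides are represented as fixed-width windows (default 13, i.e.
+/-6 residues) centered on a phosphorylatable S/T/Y; positions beyond a
protein terminus carry the padding symbol ``_``, which never counts
toward any frequency. Motifs are grown greedily: at each step every
unfixed (position, residue) candidate is scored with an exact upper-tail
binomial test of its foreground occurrence against the (conditional)
background frequency, the most significant candidate is fixed if it
clears the occurrence and significance thresholds, and when no candidate
qualifies the motif is emitted, its matching windows removed, and the
search restarts.
"""

from __future__ import annotations

from dataclasses import dataclass

from scipy.stats import binom

PAD = "_"
AA20 = "ACDEFGHIKLMNPQRSTVWY"


@dataclass(frozen=True)
class MotifResult:
    """One enriched motif: fixed residues by offset (center excluded),
    the central residue, and the statistics of its final fixing step."""

    motif: dict[int, str]
    central_residue: str
    fold_enrichment: float
    p_value: float
    foreground_matches: int

    def pattern(self) -> str:
        """sP-style string, e.g. 'R..sP' for {-3: R, +1: P} on serine."""
        half = max([abs(p) for p in self.motif], default=1)
        chars = ["."] * (2 * half + 1)
        chars[half] = self.central_residue.lower()
        for pos, res in self.motif.items():
            chars[half + pos] = res
        return "".join(chars).strip(".") or self.central_residue.lower()


def extract_windows(
    sequences: dict[str, str],
    sites: list[tuple[str, int]],
    halfwidth: int = 6,
) -> list[str]:
    """Windows of width 2*halfwidth+1 around 1-based site positions.

    Every site must index an S/T/Y; flanks extending past a protein end
    are padded with ``_``.
    """
    bad = [
        (pid, pos) for pid, pos in sites
        if sequences[pid][pos - 1] not in "STY"
    ]
    if bad:
        raise ValueError(f"sites not on S/T/Y: {bad}")
    out = []
    for pid, pos in sites:
        seq = sequences[pid]
        i = pos - 1
        left = seq[max(0, i - halfwidth): i]
        right = seq[i + 1: i + 1 + halfwidth]
        window = (PAD * (halfwidth - len(left)) + left + seq[i]
                  + right + PAD * (halfwidth - len(right)))
        out.append(window)
    return out


def binom_tail(k: int, n: int, p: float) -> float:
    """Exact upper-tail binomial probability P(X >= k) for X ~ Bin(n, p)."""
    if not 0 <= k <= n:
        raise ValueError("need 0 <= k <= n")
    if not 0 <= p <= 1:
        raise ValueError("p must lie in [0, 1]")
    if k == 0:
        return 1.0
    return float(binom.sf(k - 1, n, p))


def _matches(window: str, half: int, fixed: dict[int, str]) -> bool:
    return all(window[half + pos] == res for pos, res in fixed.items())


def motifx(
    foreground: list[str],
    background: list[str],
    central_residue: str,
    min_occurrence: int = 4,
    p_threshold: float = 1e-6,
    conditional_background: bool = True,
) -> list[MotifResult]:
    """Greedy recursive motif extraction from phosphosite windows.

    At each step, for every unfixed (position, residue): k = foreground
    windows matching the fixed residues plus the candidate, n = foreground
    windows matching the fixed residues, p = background frequency of the
    candidate residue at that position (among background windows matching
    the fixed residues when ``conditional_background``, else marginally).
    The candidate with the smallest binomial tail is fixed if its tail is
    below ``p_threshold`` and k >= ``min_occurrence``; ties break by
    smaller |position|, then position, then residue. When no candidate
    qualifies, a nonempty motif is emitted, matching foreground and
    background windows are removed, and the search restarts.
    """
    if not foreground:
        raise ValueError("foreground window set is empty")
    width = len(foreground[0])
    if any(len(w) != width for w in foreground + background):
        raise ValueError("all windows must share one width")
    half = width // 2
    if any(w[half] != central_residue for w in foreground):
        raise ValueError(f"all foreground windows must center on {central_residue!r}")
    fore = [w for w in foreground]
    back = [w for w in background if w[half] == central_residue]
    positions = [p for p in range(-half, half + 1) if p != 0]
    results: list[MotifResult] = []

    while fore:
        fixed: dict[int, str] = {}
        last_step: tuple[float, int, float] | None = None  # (p_value, k, fold)
        while True:
            fg_pool = [w for w in fore if _matches(w, half, fixed)]
            if conditional_background:
                bg_pool = [w for w in back if _matches(w, half, fixed)]
            else:
                bg_pool = back
            n = len(fg_pool)
            if n == 0:
                break
            best = None  # (p_value, |pos|, pos, res, k, bg_freq)
            for pos in positions:
                if pos in fixed:
                    continue
                bg_col = [w[half + pos] for w in bg_pool if w[half + pos] != PAD]
                if not bg_col:
                    continue
                fg_counts: dict[str, int] = {}
                for w in fg_pool:
                    c = w[half + pos]
                    if c != PAD:
                        fg_counts[c] = fg_counts.get(c, 0) + 1
                for res in AA20:
                    k = fg_counts.get(res, 0)
                    if k < min_occurrence:
                        continue
                    p_bg = bg_col.count(res) / len(bg_col)
                    if p_bg == 0.0:
                        # residue absent from the background pool: the
                        # binomial test is not scorable against it
                        continue
                    pv = binom_tail(k, n, p_bg)
                    key = (pv, abs(pos), pos, res)
                    if best is None or key < (best[0], best[1], best[2], best[3]):
                        best = (pv, abs(pos), pos, res, k, p_bg)
            if best is None or best[0] >= p_threshold:
                break
            pv, _, pos, res, k, p_bg = best
            fixed[pos] = res
            fold = (k / n) / p_bg if p_bg > 0 else float("inf")
            last_step = (pv, k, fold)
        if not fixed:
            break
        fg_match = [w for w in fore if _matches(w, half, fixed)]
        pv, k, fold = last_step
        results.append(MotifResult(
            motif=dict(sorted(fixed.items())),
            central_residue=central_residue,
            fold_enrichment=fold,
            p_value=pv,
            foreground_matches=len(fg_match),
        ))
        fore = [w for w in fore if not _matches(w, half, fixed)]
        back = [w for w in back if not _matches(w, half, fixed)]
    return results


def site_composition(sites) -> dict[str, float]:
    """Fractions of phospho-S/T/Y among site labels (sum to 1).

    Accepts residue labels ('S'/'T'/'Y') or windows (central residue
    used)."""
    sites = list(sites)
    if not sites:
        raise ValueError("no sites given")
    labels = []
    for s in sites:
        lab = s if len(s) == 1 else s[len(s) // 2]
        if lab not in "STY":
            raise ValueError(f"site label {lab!r} is not S/T/Y")
        labels.append(lab)
    n = len(labels)
    return {r: labels.count(r) / n for r in "STY"}
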