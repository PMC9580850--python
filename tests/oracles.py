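"""Independent brute-force oracles used by the test suite.

Each oracle re-derives an expected result by exhaustive search or a
straight-line reimplementation, independently of the production code
paths it checks (shared, frozen parameter tables are used where the
model's table *is* the contract).
"""

from __future__ import annotations

import math

from bsjprimer.folding import PAIR_TYPE, STACK, hairpin_penalty
from bsjprimer.seq import encode, revcomp


# ---------------------------------------------------------------- folding

def _pairable(a: int, b: int) -> bool:
    return PAIR_TYPE[a, b] >= 0


def enumerate_structures(code, i, j):
    """Yield every pseudoknot-free pair set on code[i..j] (min loop 3)."""
    if j - i < 4:
        yield frozenset()
        return
    yield from enumerate_structures(code, i + 1, j)
    for k in range(i + 4, j + 1):
        if _pairable(code[i], code[k]):
            for a in enumerate_structures(code, i + 1, k - 1):
                for b in enumerate_structures(code, k + 1, j):
                    yield frozenset({(i, k)}) | a | b


def structure_energy(code, pairs) -> float:
    """Energy of a pair set under the reduced-structure model: only
    helices of >= 3 stacked pairs contribute (stack sum + hairpin
    penalty when no contributing pair lies strictly inside the
    innermost pair)."""
    ps = set(pairs)

    def full_chain(p):
        chain = [p]
        while (chain[-1][0] + 1, chain[-1][1] - 1) in ps:
            chain.append((chain[-1][0] + 1, chain[-1][1] - 1))
        while (chain[0][0] - 1, chain[0][1] + 1) in ps:
            chain.insert(0, (chain[0][0] - 1, chain[0][1] + 1))
        return chain

    energy = 0.0
    for (i, j) in ps:
        if (i - 1, j + 1) in ps:
            continue  # not the outer pair of its helix
        chain = full_chain((i, j))
        if len(chain) < 3:
            continue
        for (a, b), (c, d) in zip(chain, chain[1:]):
            energy += STACK[PAIR_TYPE[code[a], code[b]], PAIR_TYPE[code[c], code[d]]]
        ai, aj = chain[-1]
        inside = [(x, y) for (x, y) in ps if ai < x and y < aj]
        if not any(len(full_chain(p)) >= 3 for p in inside):
            energy += hairpin_penalty(aj - ai - 1)
    return energy


def brute_force_mfe(seq: str) -> float:
    """Exhaustive minimum free energy over all structures (<= ~14 nt)."""
    code = encode(seq)
    n = len(seq)
    best = 0.0
    for s in enumerate_structures(code, 0, n - 1):
        e = structure_energy(code, s)
        if e < best:
            best = e
    return best


# ----------------------------------------------------------------- thermo

_NN = {
    "AA": (-7.9, -22.2), "TT": (-7.9, -22.2),
    "AT": (-7.2, -20.4), "TA": (-7.2, -21.3),
    "CA": (-8.5, -22.7), "TG": (-8.5, -22.7),
    "GT": (-8.4, -22.4), "AC": (-8.4, -22.4),
    "CT": (-7.8, -21.0), "AG": (-7.8, -21.0),
    "GA": (-8.2, -22.2), "TC": (-8.2, -22.2),
    "CG": (-10.6, -27.2), "GC": (-9.8, -24.4),
    "GG": (-8.0, -19.9), "CC": (-8.0, -19.9),
}


def nn_tm_oracle(seq: str, monovalent=50.0, divalent=3.0, dntp=0.6,
                 primer_conc_nm=250.0) -> float:
    """Straight-line SantaLucia nearest-neighbor Tm reimplementation."""
    dh = sum(_NN[seq[i:i + 2]][0] for i in range(len(seq) - 1))
    ds = sum(_NN[seq[i:i + 2]][1] for i in range(len(seq) - 1))
    for t in (seq[0], seq[-1]):
        dh += 0.1 if t in "GC" else 2.3
        ds += -2.8 if t in "GC" else 4.1
    selfcomp = seq == revcomp(seq)
    if selfcomp:
        ds += -1.4
    na = monovalent + 120.0 * math.sqrt(max(divalent - dntp, 0.0))
    ds += 0.368 * (len(seq) - 1) * math.log(na / 1000.0)
    ct = primer_conc_nm * 1e-9
    x = 1.0 if selfcomp else 4.0
    return 1000.0 * dh / (ds + 1.98722 * math.log(ct / x)) - 273.15


# ----------------------------------------------------------- k-mismatch

def hamming_scan_oracle(primer: str, records: dict[str, str], max_mm: int = 3):
    """Naive full scan: every ungapped window within max_mm mismatches,
    both strands, ordered (transcript, position, strand)."""
    out = []
    plen = len(primer)
    rc = revcomp(primer)
    for tid in sorted(records):
        seq = records[tid]
        for pos in range(len(seq) - plen + 1):
            window = seq[pos:pos + plen]
            for strand, pat in (("+", primer), ("-", rc)):
                mm = sum(1 for a, b in zip(window, pat) if a != b or a == "N")
                if mm <= max_mm:
                    out.append((tid, pos, strand, mm))
    return out


# ------------------------------------------------------------- exon walk

def exon_walk_oracle(exons, start, end):
    """Genomic positions inside [start, end) covered by exons, one by one."""
    return [p for p in range(start, end)
            if any(s <= p < e for s, e in exons)]


# ---------------------------------------------------- primer enumeration

def primer_enumeration_oracle(template, settings, snp_mode="strict"):
    """Brute-force all (fwd_start, fwd_len, rev_end, rev_len) placements
    applying every hard constraint independently; returns the full set
    (no ranking/truncation) as tuples (fwd_start, fwd_end, rev_start, rev_end).
    """
    from bsjprimer.seq import max_homopolymer_run
    from bsjprimer.thermo import gc_content, melting_temperature

    seq = template.sequence
    j = template.junction_index
    n = len(seq)
    len_min, _, len_max = settings.primer_len
    tm_min, _, tm_max = settings.primer_tm
    gc_min, _, gc_max = settings.primer_gc
    amp_min, amp_max = settings.amplicon_len
    ov = settings.junction_overlap

    def primer_ok(start, end, is_forward):
        segment = seq[start:end]
        if "N" in segment:
            return False
        flags = set().union(*template.mask[start:end])
        if "STRUCTURE" in flags:
            return False
        if snp_mode == "strict":
            if "SNP" in flags:
                return False
        else:
            half = (end - start) - (end - start) // 2
            rng = range(end - half, end) if is_forward else range(start, start + half)
            if any("SNP" in template.mask[i] for i in rng):
                return False
        oligo = segment if is_forward else revcomp(segment)
        if max_homopolymer_run(oligo) > settings.max_poly_x:
            return False
        if not gc_min <= gc_content(oligo) <= gc_max:
            return False
        tm = melting_temperature(oligo, settings.monovalent, settings.divalent,
                                 settings.dntp)
        if not tm_min <= tm <= tm_max:
            return False
        return tm

    found = set()
    for fs in range(0, n):
        for fl in range(len_min, len_max + 1):
            fe = fs + fl
            if fe > min(j + ov, n):
                continue
            ftm = primer_ok(fs, fe, True)
            if ftm is False:
                continue
            for re_ in range(max(j - ov, 0) + len_min, n + 1):
                for rl in range(len_min, len_max + 1):
                    rs = re_ - rl
                    if rs < max(j - ov, 0) or rs < fe:
                        continue
                    if not (fs <= j - 1 and re_ >= j + 1):
                        continue
                    if not amp_min <= re_ - fs <= amp_max:
                        continue
                    rtm = primer_ok(rs, re_, False)
                    if rtm is False:
                        continue
                    if abs(ftm - rtm) > settings.max_tm_diff:
                        continue
                    found.add((fs, fe, rs, re_))
    return found
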