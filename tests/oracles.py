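"""Independent brute-force oracles shared by the unit and acceptance tests.

These deliberately re-derive results from first principles (exhaustive
enumeration, plain per-record predicates) and never call the code paths
they are used to check.
"""

from triomap.roh import RohSegment
from triomap.variant_io import MISSING_CALL, GenotypeCall


def brute_force_roh(track, params):
    """Exhaustive enumeration of maximal admissible homozygous windows.

    Checks every (i, j) window directly against the run definition and
    keeps windows not contained in another admissible window, then applies
    the length/marker thresholds.
    """
    positions = [p for p, _ in track]
    calls = [c for _, c in track]
    n = len(track)

    def hom(c):
        return not c.missing and c.allele_count_alt in (0, 2)

    admissible = []
    for i in range(n):
        if not hom(calls[i]):
            continue
        n_het = n_miss = 0
        for j in range(i, n):
            if j > i and positions[j] - positions[j - 1] > params.max_gap_kb * 1000:
                break
            c = calls[j]
            if c.missing:
                n_miss += 1
            elif c.allele_count_alt == 1:
                n_het += 1
            if n_het > params.max_het_in_run or n_miss > params.max_missing_in_run:
                break
            if hom(c):
                admissible.append((i, j))
    maximal = [
        (i, j) for (i, j) in admissible
        if not any((i2 <= i and j <= j2 and (i2, j2) != (i, j)) for (i2, j2) in admissible)
    ]
    out = []
    for i, j in sorted(maximal):
        length = positions[j] - positions[i] + 1
        n_snps = j - i + 1
        if length >= params.min_length_kb * 1000 and n_snps >= params.min_snps:
            out.append(
                RohSegment(
                    sample_id="", chrom="",
                    start=positions[i], end=positions[j], n_snps=n_snps,
                    n_het=sum(1 for k in range(i, j + 1) if calls[k].is_het),
                    n_missing=sum(1 for k in range(i, j + 1) if calls[k].missing),
                )
            )
    return out


def random_track(rng, n, spacing=10_000, p_missing=0.05, p_het=0.3, p_big_gap=0.01):
    """Random genotype track with occasional large gaps, for oracle comparisons."""
    pos = 0
    track = []
    for _ in range(n):
        pos += spacing if rng.random() > p_big_gap else spacing * 200
        u = rng.random()
        if u < p_missing:
            call = MISSING_CALL
        elif u < p_missing + p_het:
            call = GenotypeCall.of(1)
        else:
            call = GenotypeCall.of(int(rng.choice([0, 2])))
        track.append((pos, call))
    return track
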