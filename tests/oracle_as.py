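"""Independent brute-force implementation of the AS-event rules.

Deliberately naive: every rule enumerates all index combinations with its
conditions written out long-hand, sharing no code with the package's
classifier.  Used as the oracle in equivalence tests.
"""

from __future__ import annotations

from homoeosplice.types import ExonChain


def naive_pair_events(a: ExonChain, b: ExonChain) -> set[tuple]:
    """(type, anchor) set distinguishing two chains, by exhaustive checks."""
    if list(a.exons) == list(b.exons):
        return set()
    found: set[tuple] = set()

    for first, second in ((a, b), (b, a)):
        ex1 = list(first.exons)
        ex2 = list(second.exons)
        in1 = [(ex1[i][1], ex1[i + 1][0]) for i in range(len(ex1) - 1)]
        in2 = [(ex2[i][1], ex2[i + 1][0]) for i in range(len(ex2) - 1)]

        # SE: internal exon of `first` absent from `second`, and `second`
        # contains the intron joining the flanking splice sites
        for i in range(len(ex1)):
            if i == 0 or i == len(ex1) - 1:
                continue
            exon = ex1[i]
            present = False
            for other in ex2:
                if other == exon:
                    present = True
            if present:
                continue
            wanted = (ex1[i - 1][1], ex1[i + 1][0])
            for intr in in2:
                if intr == wanted:
                    found.add(("SE", exon))

        # RI: intron of `first` inside a single exon of `second` whose
        # edges equal the outer edges of the intron's flanking exons
        for i in range(len(in1)):
            intron = in1[i]
            left_exon = ex1[i]
            right_exon = ex1[i + 1]
            for other in ex2:
                if other[0] == left_exon[0] and other[1] == right_exon[1]:
                    if other[0] <= intron[0] and intron[1] <= other[1]:
                        found.add(("RI", intron))

    # MXE: exclusive, disjoint internal exons with identical flanking sites
    ex_a = list(a.exons)
    ex_b = list(b.exons)
    for i in range(len(ex_a)):
        if i == 0 or i == len(ex_a) - 1:
            continue
        for j in range(len(ex_b)):
            if j == 0 or j == len(ex_b) - 1:
                continue
            ea, eb = ex_a[i], ex_b[j]
            if ea in ex_b:
                continue
            if eb in ex_a:
                continue
            disjoint = ea[1] <= eb[0] or eb[1] <= ea[0]
            if not disjoint:
                continue
            same_left = ex_a[i - 1][1] == ex_b[j - 1][1]
            same_right = ex_a[i + 1][0] == ex_b[j + 1][0]
            if same_left and same_right:
                pair = (ea, eb) if ea < eb else (eb, ea)
                found.add(("MXE", pair))

    # alternative splice sites: introns sharing exactly one boundary, with
    # the differing-side exon keeping its outer edge
    in_a = [(ex_a[i][1], ex_a[i + 1][0]) for i in range(len(ex_a) - 1)]
    in_b = [(ex_b[i][1], ex_b[i + 1][0]) for i in range(len(ex_b) - 1)]
    for i in range(len(in_a)):
        for j in range(len(in_b)):
            ia, ib = in_a[i], in_b[j]
            if ia == ib:
                continue
            if ia[1] == ib[1] and ia[0] != ib[0]:
                if ex_a[i][0] == ex_b[j][0]:
                    left_pair = (min(ia[0], ib[0]), max(ia[0], ib[0]))
                    kind = "A5SS" if a.strand == "+" else "A3SS"
                    found.add((kind, (left_pair, ia[1])))
            if ia[0] == ib[0] and ia[1] != ib[1]:
                if ex_a[i + 1][1] == ex_b[j + 1][1]:
                    right_pair = (min(ia[1], ib[1]), max(ia[1], ib[1]))
                    kind = "A3SS" if a.strand == "+" else "A5SS"
                    found.add((kind, (ia[0], right_pair)))

    # AP: identical junction sets, terminal boundaries differ
    if sorted(in_a) == sorted(in_b):
        s_a, s_b = ex_a[0][0], ex_b[0][0]
        if s_a != s_b:
            found.add(("AP", ("start", (min(s_a, s_b), max(s_a, s_b)))))
        e_a, e_b = ex_a[-1][1], ex_b[-1][1]
        if e_a != e_b:
            found.add(("AP", ("end", (min(e_a, e_b), max(e_a, e_b)))))

    if not found:
        sym = set(ex_a) ^ set(ex_b)
        found.add(("OTHER", tuple(sorted(sym))))
    return found


def naive_classify(chains: list[ExonChain]) -> set[tuple]:
    """Deduplicated (type, anchor) set over all chain pairs of one gene."""
    out: set[tuple] = set()
    for i in range(len(chains)):
        for j in range(len(chains)):
            if j <= i:
                continue
            out |= naive_pair_events(chains[i], chains[j])
    return out


def random_chain_pair(rng, n_exons: int | None = None, strand: str = "+"):
    """A pair of random small chains over a shared exon grid.

    Starts from a base chain and perturbs a copy with a random mix of exon
    drops, merges, boundary shifts, exon swaps and terminal truncations, so
    the pair space covers clean single events, combined events and messy
    differences alike.
    """
    n = int(n_exons if n_exons is not None else rng.integers(3, 7))
    pos = 0
    base = []
    for _ in range(n):
        length = int(rng.integers(30, 120))
        base.append((pos, pos + length))
        pos += length + int(rng.integers(40, 150))
    variant = [list(e) for e in base]

    n_edits = int(rng.integers(1, 3))
    for _ in range(n_edits):
        op = rng.integers(0, 6)
        if op == 0 and len(variant) > 2:  # drop internal exon
            del variant[int(rng.integers(1, len(variant) - 1))]
        elif op == 1 and len(variant) > 1:  # merge two adjacent exons
            i = int(rng.integers(0, len(variant) - 1))
            variant[i : i + 2] = [[variant[i][0], variant[i + 1][1]]]
        elif op == 2 and len(variant) > 1:  # shift an internal boundary
            i = int(rng.integers(0, len(variant) - 1))
            gap = variant[i + 1][0] - variant[i][1]
            if gap > 12:
                delta = int(rng.integers(1, min(gap - 1, 25)))
                if rng.random() < 0.5:
                    variant[i][1] += delta
                else:
                    variant[i + 1][0] -= delta
        elif op == 3 and len(variant) > 2:  # replace an internal exon
            i = int(rng.integers(1, len(variant) - 1))
            lo = variant[i - 1][1]
            hi = variant[i + 1][0]
            if hi - lo > 30:
                s = lo + int(rng.integers(5, hi - lo - 20))
                e = min(hi - 5, s + int(rng.integers(10, 60)))
                if e > s:
                    variant[i] = [s, e]
        elif op == 4:  # move a terminal boundary
            if rng.random() < 0.5:
                s, e = variant[0]
                if e - s > 12:
                    variant[0] = [s + int(rng.integers(1, 10)), e]
            else:
                s, e = variant[-1]
                if e - s > 12:
                    variant[-1] = [s, e - int(rng.integers(1, 10))]
        # op == 5: no edit (identical-chain pairs are exercised too)

    chain_a = ExonChain("g", strand, tuple(tuple(e) for e in base), "a")
    chain_b = ExonChain("g", strand, tuple(tuple(e) for e in variant), "b")
    return chain_a, chain_b
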