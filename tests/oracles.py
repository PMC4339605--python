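"""Independent oracles and tiny fixtures shared between test modules."""

import math

OBO = """format-version: 1.2

[Term]
id: GO:0008150
name: biological_process
namespace: biological_process

[Term]
id: GO:0009058
name: biosynthetic process
namespace: biological_process
is_a: GO:0008150

[Term]
id: GO:0009693
name: ethylene biosynthetic process
namespace: biological_process
is_a: GO:0009058

[Term]
id: GO:0999999
name: obsolete thing
is_obsolete: true
"""


def hypergeom_tail_oracle(k, N, K, n):
    """Exact one-sided over-representation p: direct summation of the
    hypergeometric pmf with integer binomials (independent of scipy)."""
    denom = math.comb(N, n)
    total = 0
    for i in range(k, min(K, n) + 1):
        total += math.comb(K, i) * math.comb(N - K, n - i)
    return total / denom


def annotation_world(N, K, n, k, dag=None):
    """Gene sets realizing one 2x2 table on the leaf term of OBO."""
    background = {f"g{i}" for i in range(N)}
    annotated = {f"g{i}" for i in range(K)}
    study = {f"g{i}" for i in range(k)} | {f"g{i}" for i in range(K, K + n - k)}
    annotations = {g: frozenset({"GO:0009693", "GO:0009058", "GO:0008150"}) for g in annotated}
    return study, background, annotations
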