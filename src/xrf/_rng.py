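"""Counter-based per-node RNG (splitmix64).

Candidate-feature subspaces are drawn at every tree node from a stream
seeded by ``(tree_seed, node_id)``, where node ids are assigned in
pre-order.  This makes the draw at any node a pure function of the tree
seed and the node's position, so the compiled and the pure-Python tree
growers reproduce each other bit for bit, and subspace draws do not
depend on traversal bookkeeping.
"""

from __future__ import annotations

_MASK = (1 << 64) - 1
_GOLD = 0x9E3779B97F4A7C15


def _mix(z: int) -> int:
    z &= _MASK
    z = ((z ^ (z >> 30)) * 0xBF58476D1CE4E5B9) & _MASK
    z = ((z ^ (z >> 27)) * 0x94D049BB133111EB) & _MASK
    return z ^ (z >> 31)


class NodeRng:
    """splitmix64 stream for one tree node.

    The stream is seeded as ``tree_seed + GOLD * (node_id + 1)``; each
    call to :meth:`next_uint` advances by the golden-ratio increment and
    mixes.  ``randint(n)`` maps a 64-bit draw to ``[0, n)`` by modulo
    (the bias is ~n/2^64, irrelevant here; determinism is what matters).
    """

    __slots__ = ("_s",)

    def __init__(self, tree_seed: int, node_id: int) -> None:
        self._s = (int(tree_seed) + _GOLD * (int(node_id) + 1)) & _MASK

    def next_uint(self) -> int:
        self._s = (self._s + _GOLD) & _MASK
        return _mix(self._s)

    def randint(self, n: int) -> int:
        if n <= 0:
            raise ValueError("randint requires n >= 1")
        return self.next_uint() % n


def partial_fisher_yates(pool: list, k: int, rng: NodeRng) -> list:
    """Draw ``k`` distinct items from ``pool`` (mutating a local copy).

    Mirrors the in-kernel draw: swap positions ``i`` and
    ``i + randint(len - i)`` for i = 0..k-1 and take the prefix.
    """
    arr = list(pool)
    m = len(arr)
    if k > m:
        raise ValueError("cannot draw more items than the pool holds")
    for i in range(k):
        j = i + rng.randint(m - i)
        arr[i], arr[j] = arr[j], arr[i]
    return arr[:k]
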