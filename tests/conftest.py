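import pytest

from charoptim.matrix import CharacterDef, CharacterMatrix
from charoptim.trees import PhyloTree


def build_matrix(taxa, columns, ordered=(), n_states=None, weights=None):
    """Construct a matrix from per-character column strings/lists.

    ``columns[j][i]`` is taxon i's cell for character j: an int, a
    frozenset, or one of the sentinels.
    """
    from charoptim.matrix import MISSING, INAPPLICABLE

    def to_cell(v):
        if v in ("?",):
            return MISSING
        if v in ("-",):
            return INAPPLICABLE
        if isinstance(v, frozenset):
            return v
        if isinstance(v, (set, tuple, list)):
            return frozenset(int(x) for x in v)
        return frozenset([int(v)])

    cols = [[to_cell(v) for v in col] for col in columns]
    chars = []
    for j, col in enumerate(cols):
        observed = set()
        for c in col:
            if isinstance(c, frozenset):
                observed |= c
        k = n_states[j] if n_states else max(2, (max(observed) + 1) if observed else 2)
        chars.append(
            CharacterDef(
                index=j,
                n_states=k,
                ordered=j in set(ordered),
                weight=(weights[j] if weights else 1.0),
            )
        )
    rows = [[cols[j][i] for j in range(len(cols))] for i in range(len(taxa))]
    return CharacterMatrix(taxa=list(taxa), characters=chars, rows=rows)


@pytest.fixture
def balanced_quartet():
    return PhyloTree.parse("((A,B),(C,D));")


@pytest.fixture
def pectinate_quartet():
    return PhyloTree.parse("(((A,B),C),D);")
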