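"""Bundled worked-example cluster sets.

Two small incompatible cluster families used throughout the documentation
and the reproduction script: a 9-cluster set on five taxa whose network
needs three reticulations, and a 7-cluster set on ten taxa (taxon 1 appears
in no cluster) used for the input-order stability experiment.
"""

from .clusters import ClusterSet

__all__ = ["five_taxon_example", "ten_taxon_example", "micro_example"]


def micro_example() -> ClusterSet:
    """The two-cluster set {{1,2},{2,3}}: the smallest incompatible family."""
    return ClusterSet([("1", "2"), ("2", "3")])


def five_taxon_example() -> ClusterSet:
    """Nine clusters on X = {1..5}; level-3, three reticulations."""
    return ClusterSet([
        ("1", "2"), ("1", "4"), ("3", "4"), ("1", "3", "4"), ("4", "5"),
        ("1", "2", "3", "4"), ("2", "3"), ("2", "3", "4"),
        ("2", "3", "4", "5"),
    ])


def ten_taxon_example() -> ClusterSet:
    """Seven clusters on X = {1..10} for the permutation-stability protocol."""
    return ClusterSet([
        ("7", "8", "9"),
        ("2", "3", "4", "7", "8", "10"),
        ("5", "6", "7", "8", "9"),
        ("2", "3", "4", "5", "6", "7", "8", "9"),
        ("2", "3", "4", "5", "6"),
        ("2", "3", "4", "10"),
        ("2", "3", "4", "5", "6", "7", "8", "10"),
    ], universe=[str(i) for i in range(1, 11)])
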