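"""Independent brute-force oracles used only by the tests.

Deliberately written without reference to the package implementation:
site classification is done by explicit membership filtering against
hard-coded residue sets and direct multiplicity counting.
"""

from alnkit.core import DataType, SiteClass

_DNA_KEEP = set("ACGT")
_AA_KEEP = set("ACDEFGHIKLMNPQRSTVWY")


def brute_force_site_class(column, datatype):
    """Classify a column by direct enumeration of state multiplicities."""
    keep = _DNA_KEEP if datatype is DataType.DNA else _AA_KEEP
    states = [c.upper() for c in column if c.upper() in keep]
    distinct = set(states)
    if len(distinct) <= 1:
        return SiteClass.CONSTANT
    with_pairs = [s for s in distinct if states.count(s) >= 2]
    if len(with_pairs) >= 2:
        return SiteClass.PARSIMONY_INFORMATIVE
    return SiteClass.VARIABLE_UNINFORMATIVE
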