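"""Exception hierarchy shared across the package.

Exit-code mapping used by the command-line layer:
InputError -> 2, NumericalError -> 3.
"""


class PhylotraceError(Exception):
    """Base class for all package errors."""

    exit_code = 1


class InputError(PhylotraceError):
    """Malformed or inconsistent input (files, labels, configuration)."""

    exit_code = 2


class NewickParseError(InputError):
    """Newick/NEXUS syntax error; message carries the offending position."""


class NumericalError(PhylotraceError):
    """Degenerate data that makes a statistic undefined (zero variance,
    single topology, empty sample)."""

    exit_code = 3
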