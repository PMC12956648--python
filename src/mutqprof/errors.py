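"""Exception hierarchy.

Every error the package raises derives from :class:`MutQProfError`, so callers
can catch one base class at pipeline boundaries while tests can assert on the
specific failure mode.
"""


class MutQProfError(Exception):
    """Base class for all mutqprof errors."""


class FormatError(MutQProfError, ValueError):
    """A string does not match the expected grammar (e.g. an HGVSp token)."""


class ResidueError(MutQProfError, ValueError):
    """An amino-acid code is not a standard residue."""


class FrameError(MutQProfError, ValueError):
    """A coding sequence whose length is not a multiple of three."""


class AlphabetError(MutQProfError, ValueError):
    """A nucleotide sequence containing characters outside {A, C, G, T}."""


class ConsistencyError(MutQProfError, ValueError):
    """Data disagrees with itself (reference mismatch, atom-count mismatch)."""


class RangeError(MutQProfError, ValueError):
    """A residue position outside the applicable sequence."""


class ClassificationError(MutQProfError, ValueError):
    """A substitution that cannot be scored (e.g. involves a stop)."""


class PDBParseError(MutQProfError, ValueError):
    """A malformed fixed-column PDB record; carries the 1-based line number."""

    def __init__(self, message: str, line_number: int | None = None):
        if line_number is not None:
            message = f"line {line_number}: {message}"
        super().__init__(message)
        self.line_number = line_number


class PairingError(MutQProfError, ValueError):
    """Atom selections that cannot be paired one-to-one."""


class DegeneracyError(MutQProfError, ValueError):
    """Too few atoms for a well-posed superposition."""


class FragmentError(MutQProfError, KeyError):
    """A fragment centre that does not exist in the structure."""


class CappingError(MutQProfError, ValueError):
    """A severed bond that cannot be capped (missing backbone atom)."""


class ChargeAssignmentError(MutQProfError, ValueError):
    """A residue with no entry in the formal side-chain charge table."""


class ManifestError(MutQProfError, ValueError):
    """A replicate manifest violating the expected slot layout."""


class EmissionError(MutQProfError, ValueError):
    """An input deck requested for an empty or invalid fragment."""


class MissingBlockError(MutQProfError, ValueError):
    """An expected output block absent or truncated in an engine output."""


class SpectrumError(MutQProfError, ValueError):
    """An orbital listing from which HOMO or LUMO cannot be defined."""


class MethodMismatchError(MutQProfError, ValueError):
    """Charge sets with different population methods mixed in one analysis."""


class AggregationError(MutQProfError, ValueError):
    """An aggregate requested over an empty collection."""


class RankError(MutQProfError, ValueError):
    """More principal components requested than the matrix rank supports."""


class SpecError(MutQProfError, ValueError):
    """An invalid fixture specification (weights, lengths, flavours)."""


class ConditioningError(MutQProfError, ValueError):
    """A rank-deficient or ill-conditioned least-squares design."""


class GridError(MutQProfError, ValueError):
    """An ESP evaluation grid violating the minimum-distance constraint."""
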