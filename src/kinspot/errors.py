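"""Exception hierarchy for kinspot.

The CLI maps these onto exit codes: input/format problems -> 2,
cross-input consistency problems -> 3.
"""


class KinspotError(Exception):
    """Base class for all kinspot errors."""


class ConfigError(KinspotError):
    """Invalid configuration value; the message names the offending field."""


class FormatError(KinspotError):
    """Malformed input file (FASTA, TSV, PDB) or unwritable value."""


class ConsistencyError(KinspotError):
    """Inputs that are individually valid but mutually inconsistent,
    e.g. the ungapped reference row and the reference structure disagree
    in length."""


class MappingError(KinspotError):
    """Unresolvable coordinate mapping, e.g. a residue that is in-domain
    in two alignment rows of the same gene."""


class ProteinChangeError(KinspotError):
    """A protein-change string that is not a single amino-acid substitution.

    ``reason`` is a machine-readable code: one of ``frameshift``,
    ``nonsense``, ``indel``, ``extension``, ``synonymous``, ``unparsable``.
    """

    def __init__(self, text: str, reason: str):
        self.text = text
        self.reason = reason
        super().__init__(f"not a single amino-acid substitution ({reason}): {text!r}")
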