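"""Exception hierarchy for the screening pipeline."""


class StatScreenError(Exception):
    """Base class for all package errors."""


class PoseFileError(StatScreenError):
    """A pose file is malformed; the message names the offending record."""


class ConsistencyError(StatScreenError):
    """Poses of one compound disagree in atom count / element sequence,
    or an object pair does not share the identity the operation requires."""


class DataError(StatScreenError):
    """A required value (score, survivor pose set, ...) is missing or invalid."""


class PocketDefinitionError(StatScreenError):
    """A pocket selection is empty or names an absent chain/residue."""


class ConfigError(StatScreenError):
    """A screening/run configuration violates its invariants."""
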