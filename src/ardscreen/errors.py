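"""Exception hierarchy shared across the package."""


class ArdscreenError(Exception):
    """Base class for all errors raised deliberately by ardscreen."""


class SchemaError(ArdscreenError):
    """A required input file or column is missing or unreadable."""


class KeyMismatchError(ArdscreenError):
    """Prediction and gold-standard patient id sets differ."""

    def __init__(self, only_pred, only_gold):
        self.only_pred = sorted(only_pred)
        self.only_gold = sorted(only_gold)
        msg = "patient id sets differ"
        if self.only_pred:
            msg += f"; only in predictions: {', '.join(self.only_pred)}"
        if self.only_gold:
            msg += f"; only in gold: {', '.join(self.only_gold)}"
        super().__init__(msg)


class ContractError(ArdscreenError):
    """A value violates an operation's stated domain (e.g. P/F ratio > 300)."""
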