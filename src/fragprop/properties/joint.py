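"""Joint distribution of two properties in one engine pass.

Pairs two plugins into one whose value is the tuple of both values.  Values
combine component-wise, boundary information is the pair of boundaries (so
fragments group by both criteria at once), and the EPC is the pair of EPCs.
Useful for joint filters such as the oral-bioavailability rule of thumb
(TPSA <= 140 Å² and <= 10 rotatable bonds), which cannot be derived from the
two marginal histograms.
"""

from __future__ import annotations

from .base import NodeContext, PropertyPlugin

__all__ = ["PairPlugin"]


class PairPlugin(PropertyPlugin):
    def __init__(self, first: PropertyPlugin, second: PropertyPlugin):
        self.first = first
        self.second = second
        self.name = f"{first.name}+{second.name}"
        self.identity = (first.identity, second.identity)
        self.context_free = first.context_free and second.context_free
        self.cache_by_default = first.cache_by_default or second.cache_by_default

    @property
    def cache_key(self) -> str:
        return f"pair({self.first.cache_key},{self.second.cache_key})"

    def combine(self, a, b):
        return (self.first.combine(a[0], b[0]), self.second.combine(a[1], b[1]))

    def fragment_ipc_boundary(self, fragment, ctx: NodeContext):
        ipc1, b1 = self.first.fragment_ipc_boundary(fragment, ctx)
        ipc2, b2 = self.second.fragment_ipc_boundary(fragment, ctx)
        return (ipc1, ipc2), (b1, b2)

    def epc(self, product, chosen, chosen_ipcs):
        first_ipcs = [v[0] for v in chosen_ipcs]
        second_ipcs = [v[1] for v in chosen_ipcs]
        return (
            self.first.epc(product, chosen, first_ipcs),
            self.second.epc(product, chosen, second_ipcs),
        )

    def sort_key(self, value):
        return (self.first.sort_key(value[0]), self.second.sort_key(value[1]))

    def format_value(self, value) -> str:
        return (
            f"{self.first.format_value(value[0])},{self.second.format_value(value[1])}"
        )
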