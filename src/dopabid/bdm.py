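"""Becker-DeGroot-Marschak (BDM) second-price auction mechanics.

The bidder states how much of a fixed water budget (default 1.2 ml) they are
willing to forgo for a juice reward, against a computer opponent whose bid is
drawn uniformly from the bid space. If the bidder's bid is greater than or
equal to the computer bid they win: they receive the juice plus the budget
remainder after paying the *computer's* bid (second-price rule). If they lose
they receive the full budget and no juice.

Bids are handled internally as fractions of the budget in [0, 1]; conversion
to ml happens only in the payout fields of :class:`AuctionOutcome`. Under the
uniform opponent the expected payoff is maximized exactly at a bid equal to
the bidder's true value, which is the incentive-compatibility property the
numeric checks in this module verify.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

__all__ = [
    "AuctionConfig",
    "AuctionOutcome",
    "resolve_auction",
    "expected_payoff",
    "expected_payoff_mc",
    "optimal_bid",
]


@dataclass(frozen=True)
class AuctionConfig:
    """Static auction parameters.

    Parameters
    ----------
    budget:
        Water endowment per trial in ml. The bid space is the closed
        interval [0, budget]; computer bids are uniform on it.
    """

    budget: float = 1.2

    def __post_init__(self) -> None:
        if not self.budget > 0:
            raise ValueError(f"budget must be positive, got {self.budget}")

    def to_dict(self) -> dict:
        return {"budget": self.budget}

    @classmethod
    def from_dict(cls, d: dict) -> "AuctionConfig":
        return cls(budget=float(d["budget"]))


@dataclass(frozen=True)
class AuctionOutcome:
    """Resolved single-trial payout.

    ``price_paid`` is the computer bid in ml on win trials and 0 on losses;
    ``water_delivered`` is the budget minus the price paid.
    """

    won: bool
    juice_delivered: float
    water_delivered: float
    price_paid: float


def _check_unit(x: float, name: str) -> None:
    if not (0.0 <= x <= 1.0):
        raise ValueError(f"{name} must lie in [0, 1] (fraction of budget), got {x}")


def resolve_auction(
    bid: float,
    computer_bid: float,
    magnitude: float,
    cfg: AuctionConfig | None = None,
) -> AuctionOutcome:
    """Resolve one auction trial.

    ``bid`` and ``computer_bid`` are fractions of the budget; ``magnitude``
    is the juice volume on offer in ml. Ties go to the bidder.
    """
    cfg = cfg or AuctionConfig()
    _check_unit(bid, "bid")
    _check_unit(computer_bid, "computer_bid")
    if magnitude < 0:
        raise ValueError(f"magnitude must be non-negative, got {magnitude}")

    if bid >= computer_bid:
        price = computer_bid * cfg.budget
        return AuctionOutcome(
            won=True,
            juice_delivered=magnitude,
            water_delivered=cfg.budget - price,
            price_paid=price,
        )
    return AuctionOutcome(won=False, juice_delivered=0.0, water_delivered=cfg.budget, price_paid=0.0)


def expected_payoff(bid: float, true_value: float, cfg: AuctionConfig | None = None) -> float:
    """Expected total payoff (ml water-equivalent) of bidding ``bid``.

    ``true_value`` is the subjective worth of the juice in ml of water. With
    a uniform opponent C on [0, 1] of the budget B, winning happens for
    C <= bid at price C·B, so

        E[payoff] = B + bid·v − B·bid²/2.

    The value is exact (closed form); :func:`expected_payoff_mc` provides the
    matching Monte-Carlo estimate for cross-checks.
    """
    cfg = cfg or AuctionConfig()
    _check_unit(bid, "bid")
    if true_value < 0:
        raise ValueError(f"true_value must be non-negative, got {true_value}")
    B = cfg.budget
    return B + bid * true_value - B * bid**2 / 2.0


def expected_payoff_mc(
    bid: float,
    true_value: float,
    cfg: AuctionConfig | None = None,
    n: int = 100_000,
    rng: np.random.Generator | None = None,
) -> tuple[float, float]:
    """Monte-Carlo estimate (mean, standard error) of the expected payoff."""
    cfg = cfg or AuctionConfig()
    _check_unit(bid, "bid")
    rng = rng or np.random.default_rng()
    c = rng.uniform(0.0, 1.0, size=n)
    won = bid >= c
    payoff = np.where(won, true_value + cfg.budget * (1.0 - c), cfg.budget)
    return float(payoff.mean()), float(payoff.std(ddof=1) / np.sqrt(n))


def optimal_bid(true_value: float, cfg: AuctionConfig | None = None) -> float:
    """Payoff-maximizing bid (fraction of budget): ``min(v / budget, 1)``.

    Values above the budget clamp to the top of the bid space; negative
    values are a domain error.
    """
    cfg = cfg or AuctionConfig()
    if true_value < 0:
        raise ValueError(f"true_value must be non-negative, got {true_value}")
    return min(true_value / cfg.budget, 1.0)
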