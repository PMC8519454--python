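"""The 15-item WHO violence-against-women (VAW) instrument.

Binary items ("yes" = 1 / "no" = 0) asking whether any male has done each act
in the past 12 months.  The WHO classifies the items into three domains:
psychological/emotional (items 1-3), physical (4-11) and sexual (12-15).
"""

from __future__ import annotations

N_ITEMS = 15
N_FACTORS = 3

FACTOR_NAMES = ("psychological", "physical", "sexual")

ITEM_LABELS = (
    "Say or do something to humiliate you in front of others?",
    "Threaten to hurt or harm you or someone close to you?",
    "Insult you or make you feel bad about yourself?",
    "Push you, shake you, or throw something at you?",
    "Slap you?",
    "Twist your arm or pull your hair?",
    "Punch you with his fist or something that could hurt you?",
    "Kick you, drag you, or beat you up?",
    "Try to choke you or burn you on purpose?",
    "Threatened to attack you with a knife or other weapon?",
    "Attacked you with a weapon?",
    "Touched you in a sexual way (e.g. kissing, grabbing, or fondling), "
    "when you did not want them to?",
    "Try to have sexual intercourse with you when you did not want to "
    "but did not succeed?",
    "Physically forced you to have sexual intercourse even when you did "
    "not want to?",
    "Forced you to perform sexual acts when you did not want to?",
)

#: item index (0-based) -> domain name
DOMAIN_MAP = {
    **{j: "psychological" for j in range(0, 3)},
    **{j: "physical" for j in range(3, 11)},
    **{j: "sexual" for j in range(11, 15)},
}

#: item index (0-based) -> major factor index (0=psych, 1=phys, 2=sexual)
MAJOR_FACTOR = tuple(FACTOR_NAMES.index(DOMAIN_MAP[j]) for j in range(N_ITEMS))

ITEM_COLUMNS = tuple(f"item{j + 1:02d}" for j in range(N_ITEMS))
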