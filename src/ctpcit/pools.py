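"""Generic word pools for stimulus construction.

English stand-ins for the category pools a concealed-information test draws
its irrelevant foils from: favourite-animal names, forenames, and month-day
dates.  The animal pool has 112 entries, matching the size of the selection
list participants typically choose a favourite animal from.
"""

from __future__ import annotations

ANIMALS: list[str] = [
    "ANTELOPE", "BADGER", "BAT", "BEAR", "BEAVER", "BEE", "BISON", "BUFFALO",
    "BUTTERFLY", "CAMEL", "CANARY", "CAT", "CHAMELEON", "CHEETAH", "CHICKEN",
    "CHIMPANZEE", "CHINCHILLA", "COBRA", "CRAB", "CRANE", "CROCODILE", "CROW",
    "DEER", "DOG", "DOLPHIN", "DONKEY", "DOVE", "DRAGONFLY", "DUCK",
    "EAGLE", "EEL", "ELEPHANT", "ELK", "FALCON", "FERRET", "FLAMINGO", "FOX",
    "FROG", "GAZELLE", "GECKO", "GIRAFFE", "GOAT", "GOOSE", "GORILLA",
    "GUINEAPIG", "HAMSTER", "HARE", "HAWK", "HEDGEHOG", "HERON", "HIPPO",
    "HORSE", "HYENA", "IGUANA", "JACKAL", "JAGUAR",
    "JELLYFISH", "KANGAROO", "KINGFISHER", "KIWI", "KOALA", "LEMUR",
    "LEOPARD", "LION", "LIZARD", "LLAMA", "LOBSTER", "LYNX", "MAGPIE", 
    "MEERKAT", "MOLE", "MONGOOSE", "MONKEY", "MOOSE", "MOUSE", 
    "NIGHTINGALE", "OCTOPUS", "OSTRICH", "OTTER", "OWL", "PANDA", "PANTHER",
    "PARROT", "PEACOCK", "PELICAN", "PENGUIN", "PHEASANT", "PIG", "PIGEON",
    "RABBIT", "RACCOON", "RAVEN", "REINDEER", "RHINO", "ROBIN",
    "SALAMANDER", "SEAL", "SHARK", "SHEEP", "SPARROW", "SQUIRREL",
    "STORK", "SWAN", "TIGER", "TORTOISE", "TOUCAN", "TURTLE", "WEASEL",
    "WHALE", "WOLF", "WOMBAT", "ZEBRA",
]

FORENAMES: list[str] = [
    "ANNA", "ALEXANDER", "AMELIA", "ANDREW", "ANGELA", "ANTON", "BARBARA",
    "BENJAMIN", "BRIGITTE", "CAROLINE", "CHARLOTTE", "CHRISTIAN", "CLARA",
    "DANIEL", "DAVID", "DIANA", "DOMINIK", "EDWARD", "ELENA", "ELIAS",
    "EMILY", "ERIK", "EVA", "FELIX", "FIONA", "FLORIAN", "FRANCESCA",
    "GABRIEL", "GEORGE", "GRETA", "HANNAH", "HELENA", "HENRY", "IRENE",
    "ISABELLA", "JACOB", "JASMIN", "JOHANNA", "JONAS", "JULIA", "KATHARINA",
    "KEVIN", "KLARA", "LAURA", "LEON", "LILLY", "LINDA", "LUCAS", "MARIA",
    "MARKUS", "MARTIN", "MATTHIAS", "MAXIMILIAN", "MELANIE", "MICHAEL",
    "MONIKA", "NATALIE", "NICOLAS", "NINA", "OLIVER", "OSCAR", "PATRICIA",
    "PAUL", "PETER", "PHILIPP", "QUENTIN", "RAPHAEL", "REBECCA", "RICHARD",
    "ROBERT", "ROSA", "SANDRA", "SEBASTIAN", "SIMON", "SOPHIA", "STEFAN",
    "SUSANNE", "TERESA", "THOMAS", "TOBIAS", "ULRIKE", "VALENTINA", "VERENA",
    "VICTOR", "VIOLA", "WERNER", "WILLIAM", "XAVER", "YVONNE", "ZOE",
]

MONTHS: list[str] = [
    "JAN", "FEB", "MAR", "APR", "MAY", "JUN",
    "JUL", "AUG", "SEP", "OCT", "NOV", "DEC",
]

# Secondary-task item texts.  Standard: five-digit number strings; Induced:
# self-referring target words vs. other-referring nontarget words.
STANDARD_TARGETS: list[str] = ["88888", "99999"]
STANDARD_NONTARGETS: list[str] = ["11111", "22222", "33333", "44444"]
INDUCER_TARGETS: list[str] = ["MINE", "FAMILIAR"]
INDUCER_NONTARGETS: list[str] = ["OTHER", "MISC", "FOREIGN", "IRRELEVANT"]


def date_text(month: int, day: int) -> str:
    """Mixed-character date item like ``'JUN 19'`` (1-based month)."""
    return f"{MONTHS[month - 1]} {day}"


def date_pool(exclude: str | None = None) -> list[str]:
    """All 366 month-day combinations, optionally minus the probe date."""
    days = [31, 29, 31, 30, 31, 30, 31, 31, 30, 31, 30, 31]
    out = [date_text(m, d) for m in range(1, 13) for d in range(1, days[m - 1] + 1)]
    if exclude is not None:
        out = [t for t in out if t != exclude]
    return out
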