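"""Bundled emoji -> ASCII shortcode table for text normalization.

Consultation posts scraped from health Q&A platforms carry emoji; models and
annotation offsets want plain text, so emoji are replaced by colon-delimited
shortcodes (CLDR-style names).  The bundled table covers emoji commonly seen
in patient messages; any other codepoint in the emoji blocks maps to the
generic ":emoji:" placeholder.
"""

SHORTCODES: dict[str, str] = {
    "\U0001F600": "grinning_face",
    "\U0001F601": "beaming_face_with_smiling_eyes",
    "\U0001F602": "face_with_tears_of_joy",
    "\U0001F603": "grinning_face_with_big_eyes",
    "\U0001F604": "grinning_face_with_smiling_eyes",
    "\U0001F605": "grinning_face_with_sweat",
    "\U0001F606": "grinning_squinting_face",
    "\U0001F609": "winking_face",
    "\U0001F60A": "smiling_face_with_smiling_eyes",
    "\U0001F60D": "smiling_face_with_heart_eyes",
    "\U0001F612": "unamused_face",
    "\U0001F614": "pensive_face",
    "\U0001F618": "face_blowing_a_kiss",
    "\U0001F622": "crying_face",
    "\U0001F625": "sad_but_relieved_face",
    "\U0001F628": "fearful_face",
    "\U0001F62D": "loudly_crying_face",
    "\U0001F630": "anxious_face_with_sweat",
    "\U0001F631": "face_screaming_in_fear",
    "\U0001F637": "face_with_medical_mask",
    "\U0001F64F": "folded_hands",
    "\U0001F44D": "thumbs_up",
    "\U0001F44C": "ok_hand",
    "\U0001F494": "broken_heart",
    "\U00002764": "red_heart",
    "\U0001F915": "face_with_head_bandage",
    "\U0001F912": "face_with_thermometer",
    "\U0001F922": "nauseated_face",
    "\U0001F927": "sneezing_face",
    "\U0001F4AA": "flexed_biceps",
    "\U0001F338": "cherry_blossom",
    "\U0001F339": "rose",
    "\U00002705": "check_mark_button",
    "\U00002753": "red_question_mark",
}

# codepoint ranges treated as emoji when not in the table above
EMOJI_RANGES: tuple[tuple[int, int], ...] = (
    (0x1F300, 0x1F5FF),   # symbols & pictographs
    (0x1F600, 0x1F64F),   # emoticons
    (0x1F680, 0x1F6FF),   # transport & map
    (0x1F900, 0x1F9FF),   # supplemental symbols
    (0x1FA70, 0x1FAFF),   # extended-A
    (0x2600, 0x27BF),     # misc symbols & dingbats
    (0x2B00, 0x2BFF),     # arrows & stars block (stars used as ratings)
    (0xFE0F, 0xFE0F),     # variation selector-16 (dropped with the emoji)
)

GENERIC = "emoji"


def is_emoji(ch: str) -> bool:
    cp = ord(ch)
    return any(lo <= cp <= hi for lo, hi in EMOJI_RANGES) or ch in SHORTCODES


def shortcode(ch: str) -> str:
    """Colon-delimited shortcode for an emoji character."""
    return f":{SHORTCODES.get(ch, GENERIC)}:"
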