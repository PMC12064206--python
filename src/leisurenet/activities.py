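"""Default leisure-activity catalogue.

The catalogue mirrors the diary instrument of a national time-use survey:
49 leisure items spanning sleep/rest, screen media, social contact,
shopping, culture, sport and religious practice. Node labels throughout
the package are these strings; analyses are label-driven, so a custom
catalogue of any length >= 2 can be substituted in the simulation config.
"""

from __future__ import annotations

#: The 49 default leisure-activity items (activity_code values).
DEFAULT_ACTIVITIES: tuple[str, ...] = (
    "Sleeping",
    "Sleeplessness",
    "Face-to-face socializing",
    "Video/audio calls",
    "Text messages or e-mails",
    "Socializing via social networking services",
    "Community participation",
    "Attendance at religious meetings/gatherings",
    "Personal religious practice",
    "Watching live TV",
    "Watching video",
    "Listening to audio devices",
    "Searching the Internet",
    "Mobile games",
    "PC games",
    "Group games/play",
    "Board games",
    "Reading books",
    "Reading newspapers/magazines",
    "Doing nothing and resting",
    "Walking/strolling",
    "Personal exercises",
    "Ball games",
    "Team sports",
    "Swimming",
    "Jogging/running",
    "Biking and inline skating",
    "Dancing",
    "Hobbies",
    "Arts and crafts",
    "Playing musical instruments",
    "Singing/karaoke",
    "Photography",
    "Writing for leisure",
    "Gardening",
    "Pet care",
    "Purchasing goods online",
    "Purchasing goods offline",
    "Window shopping",
    "Cultural and tourism activities",
    "Attending courses for leisure",
    "Watching sports events",
    "Camping",
    "Fishing",
    "Visiting family/relatives",
    "Volunteering",
    "Drinking alcohol/social drinking",
    "Travel related to socializing and community participation",
    "Travel related to cultural and leisure activities",
)

N_DEFAULT_ACTIVITIES = len(DEFAULT_ACTIVITIES)
assert N_DEFAULT_ACTIVITIES == 49
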