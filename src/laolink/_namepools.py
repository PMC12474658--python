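"""Bundled sampling pools for the synthetic registry generator.

Small curated pools of Lao given names (Latin transliteration and Lao
script), family names, and programmatically composed village names.  Pool
content affects realism of generated data, not the correctness of any
matching property.
"""

GIVEN_NAMES_LATIN = [
    "Souksan", "Bouppha", "Khamla", "Khampheng", "Somphone", "Vilayvanh",
    "Thongchanh", "Phetsamone", "Keo", "Keomany", "Chanthavy", "Bounmy",
    "Bounthanh", "Sengdao", "Noy", "Amphone", "Anousone", "Bounsong",
    "Chansamone", "Daovone", "Douangchanh", "Inpeng", "Khamsing",
    "Khemphone", "Lamngeun", "Latsamy", "Malaythong", "Manivanh", "Nalinh",
    "Outhong", "Phonesavanh", "Phoutthasone", "Sengaloun", "Sisavath",
    "Somsanith", "Soudaphone", "Thipphavanh", "Vanhdy", "Viengkham",
    "Xaysana", "Alounny", "Bounkhong", "Chittavanh", "Dalavanh", "Ekalath",
    "Houmphanh", "Intha", "Kesone", "Khounmy", "Lattana", "Mithouna",
    "Nouphone", "Onechanh", "Phimpha", "Saysamone", "Thavisouk",
    "Vongdeuane", "Xayyavong", "Boualy", "Chanpheng", "Davanh", "Engsone",
    "Fongsamouth", "Hatsady", "Inthavong", "Kongmany", "Lienkham",
    "Mongkhoun", "Ounheuane", "Phouvanh", "Somboun", "Thidavanh",
    "Vannaly", "Aloun", "Chindavanh", "Homsombath", "Kethsana", "Oudom",
    "Phetdavanh", "Saengchanh", "Vixay", "Malee", "Dara", "Chanhthala",
    "Sengphet", "Bualoy", "Daophet", "Kaothip", "Lamphone", "Maniphone",
    "Nokeo", "Orlady", "Phaeng", "Sivilay", "Tiao", "Vongsavanh",
    "Xanamane", "Bounheng", "Chanthaboun", "Deuanchay", "Khamphoui",
]

GIVEN_NAMES_LAO = [
    "ສຸກສັນ",     # Souksan
    "ບຸບຜາ",      # Bouppha
    "ຄຳຫລ້າ",    # Khamla
    "ສົມພອນ",     # Somphone
    "ແສງດາວ",    # Sengdao
    "ຈັນທະວີ",    # Chanthavy
    "ແກ້ວ",       # Keo
    "ວິໄລວັນ",    # Vilayvanh
    "ພອນສະຫວັນ",  # Phonesavanh
    "ທອງຈັນ",     # Thongchanh
    "ບຸນມີ",      # Bounmy
    "ອຳພອນ",     # Amphone
]

FAMILY_NAMES = [
    "Vongphachanh", "Phommachanh", "Sisouphanthong", "Keomanivong",
    "Luangrath", "Chanthavongsa", "Sayavong", "Inthavongsa", "Phanthavong",
    "Douangmala", "Siphandone", "Vongsa", "Keola", "Phommasane",
    "Thammavong", "Xayasith", "Manivong", "Rattanavong", "Souvannavong",
    "Bounyavong", "Norasing", "Oudomsouk", "Phengsavanh", "Sengsourinha",
]

_VILLAGE_PREFIX = ["Na", "Phon", "Nong", "Don", "Houay",
                   "Vang", "Pak", "Tha", "Xieng", "Muang"]
_VILLAGE_SUFFIX = ["hin", "savang", "khoun", "kham", "xay",
                   "thong", "bok", "san", "deng", "noy"]

VILLAGES = [f"Ban {p}{s}" for p in _VILLAGE_PREFIX for s in _VILLAGE_SUFFIX]
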