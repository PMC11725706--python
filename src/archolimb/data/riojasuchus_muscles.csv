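acronym,name,origin_bone,origin_region,origin_level,insertion_bone,insertion_region,insertion_level
IT1,M. iliotibialis 1,ilium,"craniodorsal iliac rim (roughening)",I,tibia,"cranial tip of cnemial crest",I
IT2,M. iliotibialis 2,ilium,"mid-dorsal iliac rim (roughening)",I,tibia,"cranial tip of cnemial crest",I
IT3,M. iliotibialis 3,ilium,"caudodorsal iliac rim (roughening)",I,tibia,"cranial tip of cnemial crest",I
FMTE,M. femorotibialis externus,femur,"lateral femoral shaft, between intermuscular lines",I,tibia,"cnemial crest",I
FMTI,M. femorotibialis internus,femur,"medial femoral shaft, between intermuscular lines and other muscle scars",I,tibia,"cnemial crest",I
AMB,M. ambiens,pubis,"pubic tubercle of proximal pubis",I,tibia,"cnemial crest; secondary tendon to digital flexor origin",I
ILFB,M. iliofibularis,ilium,"lateral surface of postacetabular ilium, between IF and FTE",I,fibula,"iliofibular tubercle on lateral proximal fibular shaft",I
IF,M. iliofemoralis,ilium,"lateral surface of ilium above acetabulum",II,femur,"lesser trochanter of proximal femur",II
PIFI1,M. pubo-ischio-femoralis internus 1,ilium,"craniomedial side of preacetabular ilium",II,femur,"craniomedial proximal femoral shaft, lateral to fourth trochanter",II
PIFI2,M. pubo-ischio-femoralis internus 2,vertebrae,"dorsal vertebrae close to preacetabular ilium; lateral central surfaces",II,femur,"craniolateral proximal femur, near lesser trochanter",I'
PIT,M. pubo-ischio-tibialis,ischium,"craniolateral proximal ischial apron, craniad to other ischial muscles",II,tibia,"medial proximal tibia",I'
FTI1,M. flexor tibialis internus 1,ischium,"lateral surface of distal ischial shaft (tubercle/scar)",II',tibia,"medial proximal tibia",I'
FTI3,M. flexor tibialis internus 3,ischium,"proximal ischial tuberosity (scar)",II,tibia,"caudal proximal tibia",I'
FTE,M. flexor tibialis externus,ilium,"lateral surface of caudoventral corner of postacetabular ilium",I',tibia,"caudal proximal tibia",I'
PIFE1,M. puboischiofemoralis externus 1,pubis,"cranial surface of pubic apron",I,femur,"greater trochanter",I
PIFE2,M. puboischiofemoralis externus 2,pubis,"caudal surface of pubic apron",I,femur,"greater trochanter",I
PIFE3,M. puboischiofemoralis externus 3,ischium,"lateral surface of ischial apron, caudal to ADD1",I,femur,"greater trochanter",I
ISTR,M. ischiotrochantericus,ischium,"medial surface of ischial apron",I,femur,"lateral side of proximal-most femur, near PIFE1-3",I
CFB,M. caudofemoralis brevis,ilium,"brevis fossa of ilium, and proximal caudal vertebrae",I,femur,"caudolateral side of proximal fourth trochanter",I
CFL,M. caudofemoralis longus,vertebrae,"lateral surfaces of haemal arches/chevrons and transverse processes of proximal caudal vertebrae",I,femur,"fourth trochanter; medial pit",I
ADD1,M. adductor femoris 1,ischium,"craniolateral surface of ischial apron and shaft",I',femur,"caudomedial distal femoral shaft",I'
ADD2,M. adductor femoris 2,ischium,"caudolateral surface of dorsal ischial shaft, from scarred groove",I,femur,"caudolateral distal femoral shaft near caudal intermuscular line",I'
GI,M. gastrocnemius internus,tibia,"medial side of cnemial crest of proximal tibia",I',pes,"plantar aponeurosis to metatarsal V, process on distal tarsal 4, and calcaneal tuber, then to digits 2-4 with FDB",II'
GE,M. gastrocnemius externus,femur,"proximal to lateral femoral condyle",I',pes,"plantar aponeurosis to metatarsal V and calcaneum, then to digit 5",II'
EDL,M. extensor digitorum longus,tibia,"lateral side of the cnemial crest, distal to TA origin, and the cranial tibial shaft",II,metatarsals,"craniomedial surface of proximal metatarsal I",II
EDB,M. extensor digitorum brevis,tarsals,"cranial surfaces of proximal tarsals",II',phalanges,"dorsal surfaces of distal phalanges",II
TA,M. tibialis anterior,femur,"craniolateral side of the distal femur, and lateral cnemial crest",II,metatarsals,"craniomedial sides of proximal metatarsals II-IV",II'
FDL,M. flexor digitorum longus,fibula,"proximomedial fibula's shaft",I',phalanges,"flexor tubercles of pedal unguals II-V",I
FHL,M. flexor hallucis longus,femur,"caudolateral distal femur near GE origin, lateral cnemial crest of the tibia, fossa flexoria, and proximal fibula",II',phalanges,"flexor tubercles of pedal unguals I-IV",I
FDB,M. flexor digitorum brevis,pes,"plantar aponeurosis",II',phalanges,"flexor tubercles of pedal unguals I-V",II
FHB,M. flexor hallucis brevis,tarsals,"distal tarsals and plantar aponeurosis",II,phalanges,"caudal side of proximal digit 1, 1st phalanx; metatarsal I",II'
FL,M. fibularis longus,fibula,"lateral shaft of fibula, distal to ILFB insertion",I',metatarsals,"lateral side of metatarsal V, distal to FB, and calcaneal tuber",II
FB,M. fibularis brevis,fibula,"distalmost craniolateral shaft of fibula, distal to FL origin",I',metatarsals,"caudolateral side of metatarsal V (and IV), proximal to FL",II
PP1,M. interosseous cruris/proximal pronator profundus,tibia,"caudolateral proximal tibial shaft",II',metatarsals,"caudolateral side of metatarsal I and the process of distal tarsal IV",II
PP2,M. pronator profundus,fibula,"caudomedial fibular shaft",II',metatarsals,"caudolateral side of metatarsal I and the process of distal tarsal IV",II
FC,M. fibulocalcaneus,fibula,"caudal fibular surface, distal third",II',tarsals,"dorsal surface of calcaneal tuber",II
AHD,M. abductor hallucis dorsalis,fibula,"craniolateral side of distal fibula",II',metatarsals,"proximodorsal surface of metatarsal I, near EDL insertion",II
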