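acronym,muscle,origin,insertion,origin_level,insertion_level,origin_correlate,insertion_correlate
IT1,M. iliotibialis 1,Craniodorsal iliac rim (roughening),Cranial tip of cnemial crest of tibia,I,I',True,False
IT2,M. iliotibialis 2,Dorsal iliac rim,Cranial tip of cnemial crest of tibia,I,I',True,False
IT3,M. iliotibialis 3,Caudodorsal iliac rim (roughening),Cranial tip of cnemial crest of tibia,I,I',True,False
FMTE,M. femorotibialis externus,Lateral femoral shaft limited proximally by PIFI2 insertion,Cnemial crest of tibia,I',I',False,False
FMTI,M. femorotibialis internus,Cranial and medial femoral shaft limited proximally by PIFI1 and CFL insertions,Cnemial crest of tibia,I',I',False,False
AMB,M. ambiens,Pubic tubercle of proximal pubis,Cnemial crest of tibia,I,I',True,False
ILFB,M. iliofibularis,Lateral surface of postacetabular ilium between IF and FTE,Iliofibular tubercle/scar on craniolateral fibular midshaft,I,I,True,True
IF,M. iliofemoralis,Lateral surface of ilium above acetabulum (depression),Caudolateral side of femoral midshaft,I,II',True,False
PIFI1,M. puboischiofemoralis internus 1,Ventromedial surface of ilium and puboischiadic plate,Craniomedial proximal femoral shaft lateral to fourth trochanter (groove),II,I,True,True
PIFI2,M. puboischiofemoralis internus 2,Lumbar vertebrae close to preacetabular ilium,Craniolateral proximal femur,II,I',True,False
PIT,M. puboischiotibialis,Craniolateral proximal ischial apron,Medial (extending to caudal) proximal tibia,II,I',True,False
FTI1,M. flexor tibialis internus 1,Lateral surface of distal ischial shaft,Medial (extending to caudal) proximal tibia,II',I',False,False
FTI3,M. flexor tibialis internus 3,Proximolateral surface of ischium,Caudal (extending to lateral) proximal tibia,I',I',False,False
FTE,M. flexor tibialis externus,Caudoventral corner of postacetabular ilium (striated surface),Caudal (extending to lateral) proximal tibia,I',I',False,False
PIFE1,M. puboischiofemoralis externus 1,Cranial surface of pubic apron (striae),Greater trochanter of femur,II,I,True,True
PIFE2,M. puboischiofemoralis externus 2,Caudal surface of pubic apron,Greater trochanter of femur,II,I,True,True
PIFE3,M. puboischiofemoralis externus 3,Lateral surface of ischial apron caudal to ADD1 (longitudinal depression),Greater trochanter of femur,II,I,True,True
ISTR,M. ischiotrochantericus,Medial surface of ischial apron (depression),Lateral side of proximal-most femur near PIFE1-3 (tubercles),I,I,True,True
CFB,M. caudofemoralis brevis,Proximal caudals last sacral and medial shelf of ilium,Caudolateral side of proximal fourth trochanter (flat surface),I,I,True,True
CFL,M. caudofemoralis longus,Haemal arches and transverse processes of proximal caudal vertebrae,Fourth trochanter of femur (knob),I,I,True,True
ADD1,M. adductor femoris 1,Craniolateral surface of ischial apron cranial to PIFE3 origin,Caudomedial distal femoral shaft,I',I',False,False
ADD2,M. adductor femoris 2,Caudolateral surface of dorsal ischial shaft,Caudolateral distal femoral shaft,I',I',False,False
GI,M. gastrocnemius internus,Medial side of cnemial crest of proximal tibia,Calcaneal tuber and plantar aponeurosis to metatarsal V (tuber depression),I',II,False,True
GE,M. gastrocnemius externus,Caudolateral distal femur proximal to lateral condyle,Calcaneal tuber and plantar aponeurosis (tuber depression),I',II,False,True
EDL,M. extensor digitorum longus,Lateral side of cnemial crest distal to TA origin and cranial tibial shaft,Craniomedial surfaces of proximal metatarsals I and II,II,I',True,False
EDB,M. extensor digitorum brevis,Cranial surfaces of proximal tarsals,Dorsal surfaces of distal phalanges,I',I,False,True
TA,M. tibialis anterior,Craniolateral side of distal femur and lateral side of cnemial crest,Craniomedial sides of proximal metatarsals II-IV (depression and rugosities),I,I,True,True
FDL,M. flexor digitorum longus,Proximomedial fibular shaft,Flexor tubercles of pedal unguals I-V,I',I,False,True
FHL,M. flexor hallucis longus,Caudolateral distal femur near GE origin and cnemial crest,Flexor tubercles of pedal unguals I-V,I',I,False,True
FDB,M. flexor digitorum brevis,Plantar aponeurosis,Flexor tubercles of pedal unguals I-IV,I',I,False,True
FHB,M. flexor hallucis brevis,Distal tarsals and plantar aponeurosis,Plantar surfaces of metatarsal I and digit 1 phalanx 1,I',I',False,False
FL,M. fibularis longus,Lateral fibular shaft distal to ILFB insertion (longitudinal striae),Lateral side of metatarsal V and calcaneal tuber,I,I,True,True
FB,M. fibularis brevis,Distalmost craniolateral fibular shaft distal to FL origin (striae),Caudolateral side of metatarsal V (and IV) proximal to FL,I,I,True,True
PP1,M. interosseous cruris,Caudolateral proximal tibial shaft,Caudolateral side of metatarsal I and tarsals (distal tarsal 4 process),I',II,False,True
PP2,M. pronator profundus,Caudomedial fibular shaft,Caudolateral side of metatarsal I and tarsals (distal tarsal 4 process),I,II,True,True
FC,M. fibulocalcaneus,Caudal fibular surface distal fourth (depression),Dorsal (proximal) surface of calcaneal tuber,I,II,True,True
AHD,M. adductor hallucis dorsalis,Craniolateral side of distal fibula,Proximodorsal surface of metatarsal I near EDL insertion,I',I,False,True
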