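muscle	parameter	direction	printed_percent	p_band
biceps	Z	increase	54	<0.001
biceps	R	increase	56	<0.001
biceps	fc	increase	37	<0.001
biceps	PA	decrease	44	<0.001
biceps	Ri	increase	164	<0.001
biceps	Re	increase	36	<0.001
biceps	Xc	decrease	13	<0.05
biceps	Mc	decrease	63	<0.001
triceps	Z	increase	50	<0.001
triceps	R	increase	51	<0.001
triceps	fc	NS		NS
triceps	PA	decrease	46	<0.001
triceps	Ri	increase	121	<0.001
triceps	Re	increase	48	<0.01
triceps	Xc	decrease	18	<0.05
triceps	Mc	decrease	27	NS
abductor_pollicis_brevis	Z	NS		NS
abductor_pollicis_brevis	R	NS		NS
abductor_pollicis_brevis	fc	increase	30	<0.001
abductor_pollicis_brevis	PA	decrease	17	<0.001
abductor_pollicis_brevis	Ri	NS		NS
abductor_pollicis_brevis	Re	NS		NS
abductor_pollicis_brevis	Xc	NS		NS
abductor_pollicis_brevis	Mc	decrease	35	<0.001
trapezius	Z	increase	15	<0.01
trapezius	R	increase	16	<0.001
trapezius	fc	increase	40	<0.001
trapezius	PA	decrease	16	<0.05
trapezius	Ri	increase	33	<0.05
trapezius	Re	increase	8	<0.05
trapezius	Xc	NS		NS
trapezius	Mc	decrease	27	<0.001
rectus_femoris	Z	increase	69	<0.001
rectus_femoris	R	increase	71	<0.001
rectus_femoris	fc	increase	62	<0.001
rectus_femoris	PA	decrease	52	<0.001
rectus_femoris	Ri	increase	190	<0.001
rectus_femoris	Re	increase	50	<0.001
rectus_femoris	Xc	decrease	14	<0.01
rectus_femoris	Mc	decrease	45	<0.05
vastus_lateralis	Z	increase	80	<0.001
vastus_lateralis	R	increase	85	<0.001
vastus_lateralis	fc	increase	17	<0.01
vastus_lateralis	PA	decrease	63	<0.001
vastus_lateralis	Ri	increase	311	<0.001
vastus_lateralis	Re	increase	48	<0.001
vastus_lateralis	Xc	decrease	32	<0.001
vastus_lateralis	Mc	decrease	69	<0.001
gastrocnemius	Z	increase	49	<0.001
gastrocnemius	R	increase	52	<0.001
gastrocnemius	fc	increase	26	<0.01
gastrocnemius	PA	decrease	47	<0.001
gastrocnemius	Ri	increase	197	<0.001
gastrocnemius	Re	increase	36	<0.001
gastrocnemius	Xc	decrease	22	<0.001
gastrocnemius	Mc	decrease	46	<0.01
tibialis_anterior	Z	increase	53	<0.001
tibialis_anterior	R	increase	57	<0.001
tibialis_anterior	fc	increase	23	<0.01
tibialis_anterior	PA	decrease	43	<0.001
tibialis_anterior	Ri	increase	204	<0.001
tibialis_anterior	Re	increase	36	<0.001
tibialis_anterior	Xc	decrease	16	<0.01
tibialis_anterior	Mc	decrease	46	<0.001
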