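muscle	gender	parameter	mean	sd	n	unit
biceps	men	Z	86.4	19.2	25	Ω
biceps	men	R	84.2	20.2	25	Ω
biceps	men	fc	42.3	6.4	25	kHz
biceps	men	PA	13.1	5.1	25	°
biceps	men	Ri	140.8	84.6	25	Ω
biceps	men	Re	114.0	19.2	25	Ω
biceps	men	Xc	18.1	3.7	25	Ω
biceps	men	Mc	17.5	7.6	25	pF
biceps	women	Z	133.0	27.6	25	Ω
biceps	women	R	131.9	28.1	25	Ω
biceps	women	fc	58.1	8.0	25	kHz
biceps	women	PA	7.3	3.1	25	°
biceps	women	Ri	372.4	211.7	25	Ω
biceps	women	Re	154.9	26.9	25	Ω
biceps	women	Xc	15.7	4.3	25	Ω
biceps	women	Mc	6.4	3.0	25	pF
triceps	men	Z	102.8	19.4	25	Ω
triceps	men	R	101.4	20.1	25	Ω
triceps	men	fc	30.9	6.3	25	kHz
triceps	men	PA	9.1	3.9	25	°
triceps	men	Ri	258.9	123.0	25	Ω
triceps	men	Re	131.8	18.5	25	Ω
triceps	men	Xc	15.2	4.1	25	Ω
triceps	men	Mc	15.5	6.6	25	pF
triceps	women	Z	154.1	31.2	25	Ω
triceps	women	R	153.5	31.4	25	Ω
triceps	women	fc	63.3	95.4	25	kHz
triceps	women	PA	4.8	2.1	25	°
triceps	women	Ri	573.4	288.4	25	Ω
triceps	women	Re	195.9	116.0	25	Ω
triceps	women	Xc	12.5	4.1	25	Ω
triceps	women	Mc	11.3	28.6	25	pF
abductor_pollicis_brevis	men	Z	42.8	6.4	25	Ω
abductor_pollicis_brevis	men	R	42.2	6.2	25	Ω
abductor_pollicis_brevis	men	fc	73.5	14.1	25	kHz
abductor_pollicis_brevis	men	PA	8.8	1.9	25	°
abductor_pollicis_brevis	men	Ri	78.6	20.7	25	Ω
abductor_pollicis_brevis	men	Re	50.6	9.1	25	Ω
abductor_pollicis_brevis	men	Xc	6.6	2.0	25	Ω
abductor_pollicis_brevis	men	Mc	17.8	4.0	25	pF
abductor_pollicis_brevis	women	Z	52.2	25.8	25	Ω
abductor_pollicis_brevis	women	R	51.7	25.8	25	Ω
abductor_pollicis_brevis	women	fc	95.9	19.8	25	kHz
abductor_pollicis_brevis	women	PA	7.3	1.9	25	°
abductor_pollicis_brevis	women	Ri	133.9	214.7	25	Ω
abductor_pollicis_brevis	women	Re	59.2	27.1	25	Ω
abductor_pollicis_brevis	women	Xc	6.3	1.9	25	Ω
abductor_pollicis_brevis	women	Mc	11.6	3.7	25	pF
trapezius	men	Z	71.7	15.4	25	Ω
trapezius	men	R	70.4	15.9	25	Ω
trapezius	men	fc	45.1	7.2	25	kHz
trapezius	men	PA	10.6	4.6	25	°
trapezius	men	Ri	144.5	90.9	25	Ω
trapezius	men	Re	90.8	15.1	25	Ω
trapezius	men	Xc	12.3	3.6	25	Ω
trapezius	men	Mc	18.2	8.5	25	pF
trapezius	women	Z	82.7	17.4	25	Ω
trapezius	women	R	81.7	17.8	25	Ω
trapezius	women	fc	63.2	18.9	25	kHz
trapezius	women	PA	8.9	3.7	25	°
trapezius	women	Ri	193.0	148.0	25	Ω
trapezius	women	Re	98.5	17.7	25	Ω
trapezius	women	Xc	12.0	3.7	25	Ω
trapezius	women	Mc	13.3	12.1	25	pF
rectus_femoris	men	Z	83.1	16.1	25	Ω
rectus_femoris	men	R	81.7	16.6	25	Ω
rectus_femoris	men	fc	33.2	4.2	25	kHz
rectus_femoris	men	PA	10.5	3.5	25	°
rectus_femoris	men	Ri	173.9	73.5	25	Ω
rectus_femoris	men	Re	108.5	17.0	25	Ω
rectus_femoris	men	Xc	14.4	2.5	25	Ω
rectus_femoris	men	Mc	18.8	6.0	25	pF
rectus_femoris	women	Z	140.9	19.2	25	Ω
rectus_femoris	women	R	140.4	19.1	25	Ω
rectus_femoris	women	fc	53.7	69.3	25	kHz
rectus_femoris	women	PA	5.0	1.2	25	°
rectus_femoris	women	Ri	505.1	164.2	25	Ω
rectus_femoris	women	Re	163.3	23.9	25	Ω
rectus_femoris	women	Xc	12.3	3.4	25	Ω
rectus_femoris	women	Mc	10.2	19.7	25	pF
vastus_lateralis	men	Z	68.9	15.9	25	Ω
vastus_lateralis	men	R	66.6	16.4	25	Ω
vastus_lateralis	men	fc	31.8	4.2	25	kHz
vastus_lateralis	men	PA	15.1	4.4	25	°
vastus_lateralis	men	Ri	106.1	65.7	25	Ω
vastus_lateralis	men	Re	98.2	18.3	25	Ω
vastus_lateralis	men	Xc	17.1	3.4	25	Ω
vastus_lateralis	men	Mc	27.4	7.8	25	pF
vastus_lateralis	women	Z	124.0	23.0	25	Ω
vastus_lateralis	women	R	123.4	23.0	25	Ω
vastus_lateralis	women	fc	37.3	8.4	25	kHz
vastus_lateralis	women	PA	5.5	2.0	25	°
vastus_lateralis	women	Ri	436.7	155.6	25	Ω
vastus_lateralis	women	Re	146.0	27.2	25	Ω
vastus_lateralis	women	Xc	11.6	3.9	25	Ω
vastus_lateralis	women	Mc	8.4	3.6	25	pF
gastrocnemius	men	Z	68.2	13.4	25	Ω
gastrocnemius	men	R	66.6	13.3	25	Ω
gastrocnemius	men	fc	52.5	7.9	25	kHz
gastrocnemius	men	PA	12.2	2.8	25	°
gastrocnemius	men	Ri	100.3	38.1	25	Ω
gastrocnemius	men	Re	85.6	16.9	25	Ω
gastrocnemius	men	Xc	14.2	3.8	25	Ω
gastrocnemius	men	Mc	17.7	4.8	25	pF
gastrocnemius	women	Z	102.1	20.6	25	Ω
gastrocnemius	women	R	101.5	20.6	25	Ω
gastrocnemius	women	fc	66.5	20.3	25	kHz
gastrocnemius	women	PA	6.4	1.7	25	°
gastrocnemius	women	Ri	298.5	116.7	25	Ω
gastrocnemius	women	Re	116.6	22.4	25	Ω
gastrocnemius	women	Xc	11.1	2.8	25	Ω
gastrocnemius	women	Mc	9.5	13.9	25	pF
tibialis_anterior	men	Z	59.3	8.0	25	Ω
tibialis_anterior	men	R	57.5	7.8	25	Ω
tibialis_anterior	men	fc	48.4	5.2	25	kHz
tibialis_anterior	men	PA	14.0	1.8	25	°
tibialis_anterior	men	Ri	72.8	18.4	25	Ω
tibialis_anterior	men	Re	78.6	10.6	25	Ω
tibialis_anterior	men	Xc	14.3	2.4	25	Ω
tibialis_anterior	men	Mc	22.6	4.5	25	pF
tibialis_anterior	women	Z	91.1	20.5	25	Ω
tibialis_anterior	women	R	90.2	20.6	25	Ω
tibialis_anterior	women	fc	59.7	16.3	25	kHz
tibialis_anterior	women	PA	7.9	2.5	25	°
tibialis_anterior	women	Ri	221.7	105.7	25	Ω
tibialis_anterior	women	Re	107.4	22.3	25	Ω
tibialis_anterior	women	Xc	12.1	2.8	25	Ω
tibialis_anterior	women	Mc	12.2	12.8	25	pF
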